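"""Reading/writing the NONMEM-style CSV dialect and covariate preparation.

The on-disk layout follows NONMEM conventions: one row per event, ``EVID=1``
for dosing records (with ``AMT`` and ``DUR``), ``EVID=0``/``MDV=0`` for
observations (``DV``).  A column-mapping dialect allows files with other
header names.  Missing serum creatinine is written as an empty cell and
imputed with the cohort mean (standard practice when the missing rate is
low, ≤5%).
"""
from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .datamodel import (
    LLOQ,
    Covariates,
    DoseEvent,
    Observation,
    PKDataset,
    SubjectRecord,
    ValidationError,
    is_missing,
)

__all__ = [
    "DEFAULT_DIALECT",
    "FormatError",
    "read_dataset",
    "write_dataset",
    "impute_missing_scr",
    "handle_blq",
]

logger = logging.getLogger(__name__)

#: Canonical field -> CSV column name.
DEFAULT_DIALECT = {
    "id": "ID",
    "time": "TIME",
    "amt": "AMT",
    "dur": "DUR",
    "rate": "RATE",
    "dv": "DV",
    "evid": "EVID",
    "mdv": "MDV",
    "wt": "WT",
    "pma": "PMA",
    "ga": "GA",
    "pna": "PNA",
    "scr": "SCR",
    "sex": "SEX",
}

_MANDATORY = ("id", "time", "amt", "dv", "evid", "mdv", "wt", "pma", "ga", "pna", "sex")
_COVARIATE_FIELDS = ("wt", "pma", "ga", "pna", "scr", "sex")


class FormatError(ValueError):
    """The CSV file does not conform to the expected dialect."""


def read_dataset(path, dialect_config: dict | None = None) -> PKDataset:
    """Read a NONMEM-style CSV file into a validated :class:`PKDataset`.

    Rows with ``EVID=1`` become dose events; rows with ``EVID=0`` and
    ``MDV=0`` become observations.  Observations with DV below the LLOQ
    (0.25 mg/L) are flagged BLQ.  Infusion duration is taken from ``DUR``
    if present, else derived from ``RATE``.
    """
    dialect = dict(DEFAULT_DIALECT)
    if dialect_config:
        dialect.update(dialect_config)
    df = pd.read_csv(path)

    for key in _MANDATORY:
        if dialect[key] not in df.columns:
            raise FormatError(f"missing mandatory column {dialect[key]!r}")
    has_dur = dialect["dur"] in df.columns
    has_rate = dialect["rate"] in df.columns
    if not (has_dur or has_rate):
        raise FormatError(
            f"missing column {dialect['dur']!r} (or {dialect['rate']!r}): "
            "infusion duration cannot be determined"
        )

    subjects = []
    for sid, grp in df.groupby(dialect["id"], sort=False):
        times = grp[dialect["time"]].to_numpy(float)
        if np.any(np.diff(times) < 0):
            raise ValidationError(f"subject {sid}: event times are not non-decreasing")
        cov_kwargs = {}
        for f in _COVARIATE_FIELDS:
            col = dialect[f]
            if col not in grp.columns:
                if f == "scr":
                    cov_kwargs["scr"] = None
                    continue
                raise FormatError(f"missing mandatory column {col!r}")
            vals = grp[col]
            distinct = vals.dropna().unique()
            if len(distinct) > 1:
                raise ValidationError(
                    f"subject {sid}: covariate {col} varies within subject: {distinct}"
                )
            v = vals.iloc[0]
            if f == "scr":
                cov_kwargs["scr"] = None if pd.isna(v) else float(v)
            elif f == "sex":
                cov_kwargs["sex"] = int(v)
            else:
                cov_kwargs[f] = float(v)
        cov = Covariates(**cov_kwargs)

        doses, obs = [], []
        for _, row in grp.iterrows():
            evid = int(row[dialect["evid"]])
            t = float(row[dialect["time"]])
            if evid == 1:
                amt = float(row[dialect["amt"]])
                if has_dur and not is_missing(float(row[dialect["dur"]])):
                    dur = float(row[dialect["dur"]])
                else:
                    dur = amt / float(row[dialect["rate"]])
                doses.append(DoseEvent(time=t, amount=amt, infusion_duration=dur))
            elif evid == 0 and int(row[dialect["mdv"]]) == 0:
                dv = float(row[dialect["dv"]])
                obs.append(Observation(time=t, conc=dv, blq_flag=dv < LLOQ))
        subjects.append(
            SubjectRecord(subject_id=str(sid), covariates=cov, doses=doses, observations=obs)
        )
    return PKDataset(subjects=tuple(subjects), provenance={"source": str(path)})


def write_dataset(dataset: PKDataset, path) -> None:
    """Write a dataset back to the NONMEM-style CSV layout (lossless round trip)."""
    rows = []
    for s in dataset.subjects:
        c = s.covariates
        base = {
            "ID": s.subject_id, "WT": c.wt, "PMA": c.pma, "GA": c.ga,
            "PNA": c.pna, "SCR": c.scr if c.scr is not None else np.nan,
            "SEX": c.sex,
        }
        events = [("dose", d.time, d) for d in s.doses] + [
            ("obs", o.time, o) for o in s.observations
        ]
        events.sort(key=lambda e: (e[1], 0 if e[0] == "dose" else 1))
        for kind, t, ev in events:
            row = dict(base)
            row["TIME"] = t
            if kind == "dose":
                row.update(AMT=ev.amount, DUR=ev.infusion_duration,
                           DV=np.nan, EVID=1, MDV=1)
            else:
                row.update(AMT=np.nan, DUR=np.nan, DV=ev.conc, EVID=0, MDV=0)
            rows.append(row)
    cols = ["ID", "TIME", "AMT", "DUR", "DV", "EVID", "MDV",
            "WT", "PMA", "GA", "PNA", "SCR", "SEX"]
    pd.DataFrame(rows)[cols].to_csv(path, index=False, float_format="%.10g")


def impute_missing_scr(dataset: PKDataset) -> PKDataset:
    """Replace missing serum-creatinine values with the cohort arithmetic mean.

    One value per subject enters the mean.  The imputation count and rate
    are recorded under ``provenance['scr_imputation']``; a missing rate
    above 5% triggers a warning (mean imputation is only considered safe
    at low missing rates).
    """
    observed = [s.covariates.scr for s in dataset.subjects if not is_missing(s.covariates.scr)]
    n_missing = dataset.n_subjects - len(observed)
    if not observed:
        raise ValidationError("all SCR values missing: cannot impute")
    if n_missing == 0:
        prov = dict(dataset.provenance)
        prov["scr_imputation"] = {"n_imputed": 0, "rate_percent": 0.0, "mean": None}
        return replace(dataset, provenance=prov)

    mean_scr = float(np.mean(observed))
    rate = 100.0 * n_missing / dataset.n_subjects
    if rate > 5.0:
        logger.warning(
            "SCR missing rate %.1f%% exceeds 5%%: mean imputation may be unreliable", rate
        )
    new_subjects = []
    for s in dataset.subjects:
        if is_missing(s.covariates.scr):
            new_subjects.append(replace(s, covariates=replace(s.covariates, scr=mean_scr)))
        else:
            new_subjects.append(s)
    prov = dict(dataset.provenance)
    prov["scr_imputation"] = {
        "n_imputed": n_missing,
        "rate_percent": round(rate, 10),
        "mean": mean_scr,
    }
    return PKDataset(subjects=tuple(new_subjects), provenance=prov)


def drop_subjects_without_observations(dataset: PKDataset) -> PKDataset:
    """Remove subjects left without quantifiable observations (e.g. after
    BLQ discarding); they carry no likelihood information."""
    kept = tuple(s for s in dataset.subjects if s.observations)
    n_dropped = dataset.n_subjects - len(kept)
    if n_dropped == 0:
        return dataset
    logger.info("dropping %d subject(s) without observations", n_dropped)
    prov = dict(dataset.provenance)
    prov["subjects_dropped_no_obs"] = n_dropped
    return PKDataset(subjects=kept, provenance=prov)


def handle_blq(dataset: PKDataset, policy: str = "discard") -> PKDataset:
    """Apply a below-LLOQ policy.

    ``"discard"`` (M1) drops BLQ observations; ``"loq/2"`` (M5) replaces
    them with LLOQ/2 = 0.125 mg/L, keeping the flag.
    """
    if policy not in ("discard", "loq/2"):
        raise ValueError(f"unknown BLQ policy {policy!r}; expected 'discard' or 'loq/2'")
    n_blq = sum(o.blq_flag for s in dataset.subjects for o in s.observations)
    if n_blq == 0:
        return dataset
    logger.info("BLQ policy %r applied to %d observations", policy, n_blq)
    new_subjects = []
    for s in dataset.subjects:
        if policy == "discard":
            obs = tuple(o for o in s.observations if not o.blq_flag)
        else:
            obs = tuple(
                replace(o, conc=LLOQ / 2) if o.blq_flag else o for o in s.observations
            )
        new_subjects.append(replace(s, observations=obs))
    prov = dict(dataset.provenance)
    prov["blq_handling"] = {"policy": policy, "n_affected": n_blq}
    return PKDataset(subjects=tuple(new_subjects), provenance=prov)
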