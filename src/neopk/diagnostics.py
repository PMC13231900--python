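"""Model diagnostics: goodness-of-fit residuals, VPC, and bootstrap.

All residual work happens in the log-concentration domain, where the
exponential residual model is additive Gaussian:

* ``IWRES = (log DV - log IPRED) / sigma`` with IPRED evaluated at the
  empirical Bayes etas.
* ``CWRES`` comes from the first-order-conditional linearization of the
  subject model around the EBEs: with ``G`` the Jacobian of the
  log-prediction in eta, the subject's log-observations are approximately
  ``N(h(eta_hat) - G eta_hat, G Omega G' + sigma2 I)``; the residual
  vector is whitened by the Cholesky factor of that covariance.  Under a
  correct model CWRES are standard normal.

The visual predictive check simulates replicate datasets at the original
design and compares observed 5/50/95% quantiles per time bin with the
simulation distribution; its ``coverage`` is the percentage of observed
concentrations inside the pointwise simulated 90% prediction interval.

The nonparametric bootstrap resamples whole subjects with replacement
(the exchangeable unit of a hierarchical design), refits every
replicate, and summarises converged replicates by percentile intervals.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import PKDataset, SubjectRecord
from .estimation import (
    FitResult,
    _Cohort,
    _residual_and_jac,
    _typical_cl_v_arrays,
    cv_percent,
    fit_population,
)
from .pkmodel import PopModelParams

__all__ = ["GofTable", "VpcResult", "BootstrapResult", "gof_table", "vpc", "bootstrap"]

logger = logging.getLogger(__name__)

#: default VPC bins: the sparse-design sampling windows (h post dose)
DEFAULT_VPC_BINS = ((0.0, 0.5), (2.0, 3.0), (4.0, 6.0))

GofTable = pd.DataFrame  # alias: the GOF table is a plain tidy frame


@dataclass
class VpcResult:
    bin_edges: tuple[tuple[float, float], ...]
    bin_centers: np.ndarray
    observed_quantiles: np.ndarray   # (3, n_bins): 5/50/95%
    simulated_quantiles: np.ndarray  # (3, n_bins): median across replicates
    simulated_bands: np.ndarray      # (3, n_bins, 2): 95% CI of each curve
    coverage: float                  # % of observations inside the 90% PI
    n_sim: int
    seed: int | None


@dataclass
class BootstrapResult:
    summary: pd.DataFrame      # index: parameter; columns: median, ci_lo, ci_hi, rse_percent
    convergence_fraction: float  # %
    n_replicates: int
    seed: int | None
    estimates: pd.DataFrame    # per converged replicate


def gof_table(dataset: PKDataset, fit: FitResult) -> GofTable:
    """Per-observation diagnostics: PRED (eta=0), IPRED (EBEs), IWRES, CWRES.

    Rows appear in dataset order; subjects without observations
    contribute none.
    """
    coh = _Cohort(dataset.subjects)
    params = fit.params
    cl_typ, v_typ = _typical_cl_v_arrays(coh, params, fit.covariate_terms, fit.thetas)
    sigma = np.sqrt(params.sigma2)
    omega = np.diag([params.omega2_cl, params.omega2_v])

    ebes = fit.ebes
    if ebes.shape[0] != coh.n:
        raise ValueError(
            f"fit carries {ebes.shape[0]} EBE pairs but dataset has {coh.n} subjects"
        )
    # population predictions (eta = 0)
    r0, _ = _residual_and_jac(coh, cl_typ, v_typ, np.zeros((coh.n, 2)))
    # individual predictions and Jacobians at the EBEs
    ri, J = _residual_and_jac(coh, cl_typ, v_typ, ebes)

    rows = []
    for i, s in enumerate(dataset.subjects):
        m = int(coh.m[i])
        if m == 0:
            continue
        logy = coh.LOGY[i, :m]
        log_pred = logy - r0[i, :m]
        log_ipred = logy - ri[i, :m]
        G = -J[i, :m, :]  # d log f / d eta
        cov = G @ omega @ G.T + params.sigma2 * np.eye(m)
        # linearized population mean: h(eta_hat) - G eta_hat
        mean = log_ipred - G @ ebes[i]
        L = np.linalg.cholesky(cov)
        cwres = np.linalg.solve(L, logy - mean)
        iwres = ri[i, :m] / sigma
        for j in range(m):
            rows.append(dict(
                subject_id=s.subject_id, time=coh.T[i, j], dv=np.exp(logy[j]),
                pred=np.exp(log_pred[j]), ipred=np.exp(log_ipred[j]),
                iwres=iwres[j], cwres=cwres[j],
            ))
    return pd.DataFrame(rows)


def _assign_bins(times: np.ndarray, bins) -> np.ndarray:
    """Bin index per time: the containing window, else the nearest one."""
    idx = np.full(times.shape, -1, dtype=int)
    for b, (lo, hi) in enumerate(bins):
        idx[(times >= lo) & (times <= hi)] = b
    if np.any(idx < 0):
        centers = np.array([(lo + hi) / 2 for lo, hi in bins])
        for j in np.flatnonzero(idx < 0):
            idx[j] = int(np.argmin(np.abs(centers - times[j])))
    return idx


def _simulate_replicates(coh: _Cohort, params: PopModelParams, terms, thetas,
                         n_sim: int, rng) -> np.ndarray:
    """(n_sim, n_obs) matrix of simulated concentrations at the design points."""
    cl_typ, v_typ = _typical_cl_v_arrays(coh, params, terms, thetas)
    sims = np.empty((n_sim, int(coh.m.sum())))
    sigma = np.sqrt(params.sigma2)
    om_cl = np.sqrt(params.omega2_cl)
    om_v = np.sqrt(params.omega2_v)
    mask = coh.OMASK
    for s in range(n_sim):
        etas = np.column_stack([
            rng.normal(0.0, om_cl, size=coh.n),
            rng.normal(0.0, om_v, size=coh.n),
        ])
        r, _ = _residual_and_jac(coh, cl_typ, v_typ, etas)
        log_f = coh.LOGY - r
        eps = rng.normal(0.0, sigma, size=log_f.shape)
        sims[s] = (np.exp(log_f + eps))[mask]
    return sims


def vpc(dataset: PKDataset, params: PopModelParams, n_sim: int = 1000,
        seed=0, bins=DEFAULT_VPC_BINS, covariate_terms=(), thetas=()) -> VpcResult:
    """Visual predictive check at the original design.

    Each replicate redraws etas and residuals for the same subjects,
    doses and sampling times.  Empty bins are merged into their
    neighbour with a warning.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    coh = _Cohort(dataset.subjects)
    rng = np.random.default_rng(seed)
    times = coh.T[coh.OMASK]
    obs = np.exp(coh.LOGY[coh.OMASK])

    bins = [tuple(b) for b in bins]
    idx = _assign_bins(times, bins)
    # merge empty bins
    occupied = sorted(set(idx.tolist()))
    if len(occupied) < len(bins):
        logger.warning("VPC: %d empty time bin(s) merged", len(bins) - len(occupied))
        bins = [bins[b] for b in occupied]
        remap = {b: i for i, b in enumerate(occupied)}
        idx = np.array([remap[b] for b in idx])

    sims = _simulate_replicates(coh, params, covariate_terms, thetas, n_sim, rng)

    qs = (5.0, 50.0, 95.0)
    n_bins = len(bins)
    obs_q = np.empty((3, n_bins))
    sim_q = np.empty((3, n_bins))
    sim_bands = np.empty((3, n_bins, 2))
    for b in range(n_bins):
        sel = idx == b
        obs_q[:, b] = np.percentile(obs[sel], qs)
        rep_q = np.percentile(sims[:, sel], qs, axis=1)  # (3, n_sim)
        sim_q[:, b] = np.median(rep_q, axis=1)
        sim_bands[:, b, 0] = np.percentile(rep_q, 2.5, axis=1)
        sim_bands[:, b, 1] = np.percentile(rep_q, 97.5, axis=1)

    lo = np.percentile(sims, 5.0, axis=0)
    hi = np.percentile(sims, 95.0, axis=0)
    coverage = 100.0 * float(np.mean((obs >= lo) & (obs <= hi)))

    return VpcResult(
        bin_edges=tuple(bins),
        bin_centers=np.array([(a + c) / 2 for a, c in bins]),
        observed_quantiles=obs_q,
        simulated_quantiles=sim_q,
        simulated_bands=sim_bands,
        coverage=coverage,
        n_sim=n_sim,
        seed=seed if isinstance(seed, int) else None,
    )


_BOOT_PARAMS = ("tvcl", "tvv", "omega2_cl", "omega2_v", "sigma2")


def bootstrap(dataset: PKDataset, init: PopModelParams, n_replicates: int = 1000,
              seed=0, covariate_terms=()) -> BootstrapResult:
    """Nonparametric subject-level bootstrap of the population fit.

    Each replicate resamples the subjects with replacement (keeping the
    original cohort size and each subject's complete record), refits, and
    is counted as converged when the optimizer succeeded with all
    variance components off the boundary.  Percentile 95% intervals and
    RSE% (bootstrap sd / median estimate) summarise converged replicates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    subjects = list(dataset.subjects)
    rng = np.random.default_rng(seed)
    rows = []
    n_conv = 0
    for rep in range(n_replicates):
        take = rng.integers(0, len(subjects), size=len(subjects))
        resampled = [
            SubjectRecord(
                subject_id=f"B{rep:04d}_{j:03d}",
                covariates=subjects[t].covariates,
                doses=subjects[t].doses,
                observations=subjects[t].observations,
            )
            for j, t in enumerate(take)
        ]
        boot_ds = PKDataset(subjects=tuple(resampled),
                            provenance={"source": "bootstrap", "replicate": rep})
        try:
            fit = fit_population(boot_ds, init, covariate_terms=covariate_terms)
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            logger.warning("bootstrap replicate %d failed: %s", rep, exc)
            continue
        ok = fit.converged and not fit.boundary
        n_conv += ok
        row = {p: getattr(fit.params, p) for p in _BOOT_PARAMS}
        row["converged"] = ok
        rows.append(row)
    if not rows:
        raise RuntimeError("all bootstrap replicates failed")
    est = pd.DataFrame(rows)
    if est.converged.any():
        conv = est[est.converged].drop(columns="converged")
    else:
        logger.warning(
            "no bootstrap replicate met the strict convergence criterion; "
            "summarising all %d completed replicates", len(est)
        )
        conv = est.drop(columns="converged")
    summary = pd.DataFrame({
        "median": conv.median(),
        "ci_lo": conv.quantile(0.025),
        "ci_hi": conv.quantile(0.975),
    })
    summary["rse_percent"] = 100.0 * conv.std(ddof=1) / conv.median().abs()
    # variability terms also on the CV% scale used in reporting
    for name, col in (("iiv_cl_cv", "omega2_cl"), ("iiv_v_cv", "omega2_v"),
                      ("sigma_cv", "sigma2")):
        vals = conv[col].map(cv_percent)
        summary.loc[name] = [vals.median(), vals.quantile(0.025),
                             vals.quantile(0.975),
                             100.0 * vals.std(ddof=1) / vals.median()]
    return BootstrapResult(
        summary=summary,
        convergence_fraction=100.0 * n_conv / n_replicates,
        n_replicates=n_replicates,
        seed=seed if isinstance(seed, int) else None,
        estimates=est,
    )
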