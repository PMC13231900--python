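import pytest

from neopk import (
    Covariates,
    DoseEvent,
    Observation,
    PKDataset,
    SubjectRecord,
    final_model_params,
)


@pytest.fixture(scope="session")
def ref_params():
    return final_model_params()


@pytest.fixture
def typical_covariates():
    """A median study neonate: 3.2 kg, PMA 39.4 weeks."""
    return Covariates(wt=3.2, pma=39.4, ga=39.0, pna=2.0, scr=56.7, sex=1)


def make_subject(sid="S001", wt=3.2, pma=39.4, scr=56.7, sex=1,
                 dose_mg=80.0, obs=((0.4, 20.0), (5.0, 8.0))):
    return SubjectRecord(
        subject_id=sid,
        covariates=Covariates(wt=wt, pma=pma, ga=pma - 0.3, pna=2.0, scr=scr, sex=sex),
        doses=(DoseEvent(time=0.0, amount=dose_mg, infusion_duration=0.5),),
        observations=tuple(Observation(time=t, conc=c) for t, c in obs),
    )


@pytest.fixture
def two_subject_dataset():
    return PKDataset(subjects=(
        make_subject("S001"),
        make_subject("S002", wt=2.5, pma=36.0, dose_mg=62.5,
                     obs=((0.3, 25.0), (2.5, 14.0))),
    ))
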