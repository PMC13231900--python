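"""Reference model: published-style parameter values used as defaults.

These are the final population estimates of the neonatal ceftazidime
whole-blood model this package re-implements, used as the default truth
for simulation and as initial values for fitting:

======================  =======================  =====================
quantity                value                    note
======================  =======================  =====================
TVCL                    19.6 L/h/70 kg           at full maturation
TVV                     70.6 L/70 kg
IIV on CL               28.1 CV%                 omega2 = ln(1+CV^2)
IIV on V                42.4 CV%
residual (log-domain)   22.3 CV%
TM50                    47.7 weeks               fixed (renal maturation)
Hill                    3.4                      fixed
blood-to-plasma ratio   0.72
unbound fraction        0.9                      low protein binding
======================  =======================  =====================

The bootstrap 95% interval reported for the IIV-CL CV% in the source
analysis was 14.6-37.0%; it is used by the recovery checks.
"""
from __future__ import annotations

from .estimation import cv_to_omega2
from .pkmodel import PopModelParams, Regimen

__all__ = [
    "final_model_params",
    "study_regimens",
    "MIC_GRID",
    "PMA_SUBGROUPS",
    "BLOOD_TO_PLASMA_RATIO",
    "UNBOUND_FRACTION",
    "IIV_CL_CV_BOOTSTRAP_CI",
]

#: blood-to-plasma concentration ratio of ceftazidime
BLOOD_TO_PLASMA_RATIO = 0.72
#: unbound fraction in plasma (~10% protein binding)
UNBOUND_FRACTION = 0.9
#: doubling-dilution MIC grid, mg/L (EUCAST-style reporting)
MIC_GRID = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
#: postmenstrual-age subgroups for the virtual cohorts, weeks
PMA_SUBGROUPS = ((32.0, 35.0), (35.0, 38.0), (38.0, 42.0))
#: bootstrap 95% CI of the IIV-CL coefficient of variation, percent
IIV_CL_CV_BOOTSTRAP_CI = (14.6, 37.0)


def final_model_params() -> PopModelParams:
    """Reference population parameters (see module docstring)."""
    return PopModelParams(
        tvcl=19.6,
        tvv=70.6,
        omega2_cl=cv_to_omega2(28.1),
        omega2_v=cv_to_omega2(42.4),
        sigma2=cv_to_omega2(22.3),
        tm50=47.7,
        hill=3.4,
    )


def study_regimens() -> tuple[Regimen, ...]:
    """The 12-regimen evaluation grid: {25, 50, 75, 100} mg/kg x q{6, 8, 12}h,
    all as 30-min infusions."""
    return tuple(
        Regimen(dose_per_kg=d, interval=tau, infusion_duration=0.5)
        for d in (25.0, 50.0, 75.0, 100.0)
        for tau in (6.0, 8.0, 12.0)
    )
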