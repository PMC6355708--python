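import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nuc_cohort():
    """Default seven-subject cohort, fixed seed."""
    from caisotope import generate_cohort

    return generate_cohort(7, seed=11)


@pytest.fixture(scope="session")
def nuc_samples(nuc_cohort):
    """Default simulated study at measurement noise 0.05 permil."""
    from caisotope import simulate_timecourse

    return simulate_timecourse(nuc_cohort, seed=12)


@pytest.fixture(scope="session")
def flat_samples():
    """Noise-free null study: no bone response, no reabsorption modulation."""
    from caisotope import BoneResponseParams, generate_cohort, simulate_timecourse

    cohort = generate_cohort(7, seed=21)
    bone = BoneResponseParams(resorption_flux_max=0.0, f_modulation_gain=0.0)
    return simulate_timecourse(cohort, bone=bone, noise_se=0.0, seed=22)


def rayleigh_curve_samples(n=14, delta_blood=0.4, alpha=0.99975, load=220.0,
                           f_lo=0.01, f_hi=0.045, phase="BDC"):
    """Noise-free samples lying exactly on one Rayleigh curve."""
    import math

    from caisotope import UrineSample

    fs = np.exp(np.linspace(math.log(f_lo), math.log(f_hi), n))
    return [
        UrineSample(
            subject_id=f"S{i:02d}",
            day_label="BDC-2",
            phase=phase,
            delta_urine=(delta_blood + 1000.0) * f ** (alpha - 1.0) - 1000.0,
            se=0.0,
            ca_excreted=load * f,
        )
        for i, f in enumerate(fs)
    ]
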