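import numpy as np
import pytest

from ppgchaos.preprocess import VitalRecord, preprocess_record
from ppgchaos.wk4 import SimConfig, simulate_wk4


@pytest.fixture(scope="session")
def sim_noiseless():
    """70 s noiseless constant-parameter WK4 simulation (HR 60, SV 70)."""
    return simulate_wk4(SimConfig(duration_s=70.0, seed=2))


@pytest.fixture(scope="session")
def vital_noiseless(sim_noiseless):
    return VitalRecord.from_simulation(sim_noiseless, subject_id="clean")


@pytest.fixture(scope="session")
def prep_noiseless(vital_noiseless):
    beats, pulsatile, baseline, wt, wb = preprocess_record(vital_noiseless)
    return {"beats": beats, "pulsatile": pulsatile, "baseline": baseline,
            "time_windows": wt, "beat_windows": wb}


@pytest.fixture(scope="session")
def sim_c1_fluct():
    """300 s simulation with OU-modulated proximal compliance (sigma 10%)."""
    return simulate_wk4(
        SimConfig(duration_s=300.0, seed=5, fluct={"C1": (0.1, 30.0)})
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
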