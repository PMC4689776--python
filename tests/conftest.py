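import numpy as np
import pytest

from qtpkpd import load_preset
from qtpkpd.params import DesignSpec, SpeciesParams


@pytest.fixture(scope="session")
def human_mox():
    return load_preset("human_moxifloxacin")


@pytest.fixture(scope="session")
def dog_mox():
    return load_preset("dog_moxifloxacin")


@pytest.fixture
def flat_params():
    """Species parameters with all variability switched off."""
    return SpeciesParams(
        qtc0_ms=399.0, sex_effect_ms=0.0, alpha=0.40, amp_ms=2.4, phase_h=10.0,
        slope_ms_per_nM=0.0039, bsv={}, resid_sd_ms=1e-12)


@pytest.fixture
def simple_design():
    return DesignSpec(
        n_subjects=4, dose_levels=[0, 100], crossover=True,
        pk_sample_times_h=[0.5, 1, 2, 4, 8, 24],
        ecg_sample_times_h=list(np.arange(0.5, 24.0, 1.0)),
        rr_baseline_ms=1000.0, rr_circadian_frac=0.1, rr_noise_frac=0.03)
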