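import numpy as np
import pytest

from bindspec import itc, synth

# Fitted parameters of the calmodulin/Orai peptide and calmodulin/ANS systems,
# reused across tests as simulation ground truths.
CAM_ONE_SET = dict(n_sites=2.05, k_a=8.92e5, dh=-5.02)
CAM1TNC_SEQ = dict(k_a1=7.57e5, dh1=-4.99, k_a2=1.70e4, dh2=-3.33)
ANS_WEAK = dict(n_sites=5.0, k_a=2.10e3, dh=-2.0)
CAM_KOFF_S = 1.41
KSV_FREE_PEPTIDE = 13.5
ANS_TAUS_NS = (6.4, 13.1, 0.3)
ANS_FRACTIONS = (0.44, 0.53)


@pytest.fixture
def peptide_schedule():
    """30 uM protein cell, 1 mM peptide syringe, 25 x 10 uL, 1.4 mL cell."""
    return itc.TitrationSchedule(
        cell_volume_L=1.4e-3, cell_conc_M=30e-6, syringe_conc_M=1e-3,
        injection_volumes_L=(10e-6,) * 25)


@pytest.fixture
def ans_schedule():
    """50 uM protein cell, 5 mM dye syringe, 27 x 10 uL (weak-binding regime)."""
    return itc.TitrationSchedule(
        cell_volume_L=1.4e-3, cell_conc_M=50e-6, syringe_conc_M=5e-3,
        injection_volumes_L=(10e-6,) * 27)


@pytest.fixture
def cam_model():
    return itc.BindingModel.one_set(**CAM_ONE_SET)


@pytest.fixture
def seq_model():
    return itc.BindingModel.sequential(**CAM1TNC_SEQ)


@pytest.fixture
def ans_decay_model():
    """Three-exponential ANS model: two bound-dye components plus free dye."""
    return synth.ans_cam_model()


@pytest.fixture
def rng():
    return np.random.default_rng(20150215)
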