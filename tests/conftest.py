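import numpy as np
import pytest

from mcotce import build_pwm, calibrate, demo_motif, make_calibration

ANCHOR_CONSENSUS = "TGTTTACTTA"
PARTNER_CONSENSUS = "GTTAATGATT"


@pytest.fixture(scope="session")
def anchor_motif():
    return demo_motif("AnchorM", ANCHOR_CONSENSUS)


@pytest.fixture(scope="session")
def partner_motif():
    return demo_motif("PartnerM", PARTNER_CONSENSUS)


@pytest.fixture(scope="session")
def calibration_small():
    """400 kb Markov-0 calibration set: enough windows for CL up to 5.5."""
    return make_calibration(400_000, seed=42)


@pytest.fixture(scope="session")
def anchor_calibrated(anchor_motif, calibration_small):
    pwm = build_pwm(anchor_motif, calibration_small.base_frequencies())
    return calibrate(pwm, calibration_small)


@pytest.fixture(scope="session")
def partner_calibrated(partner_motif, calibration_small):
    pwm = build_pwm(partner_motif, calibration_small.base_frequencies())
    return calibrate(pwm, calibration_small)


def random_frequency_matrix(rng, length=10, motif_id="R"):
    from mcotce import FrequencyMatrix

    cols = rng.integers(1, 50, size=(length, 4)).astype(float)
    return FrequencyMatrix(motif_id=motif_id, columns=cols, is_counts=True)
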