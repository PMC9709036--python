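"""Shared fixtures: one synthetic night computed once per session."""

import numpy as np
import pytest

from agamasleep.cycles import segment_cycles
from agamasleep.spectral import LfpSignal, delta_beta_series, preprocess_lfp
from agamasleep.synth import GenConfig, generate_recording


def circ_diff(a, b):
    """Signed circular difference a - b in (-pi, pi]."""
    return float(np.angle(np.exp(1j * (a - b))))


def match_f1(detected, truth, tol_s=0.0125):
    """Greedy one-to-one event matching; returns (f1, precision, recall)."""
    detected = np.asarray(detected, float)
    truth = np.asarray(truth, float)
    if len(detected) == 0 or len(truth) == 0:
        return 0.0, 0.0, 0.0
    used = np.zeros(len(truth), bool)
    tp = 0
    for d in detected:
        j = int(np.argmin(np.abs(truth - d)))
        if abs(truth[j] - d) <= tol_s and not used[j]:
            used[j] = True
            tp += 1
    prec = tp / len(detected)
    rec = tp / len(truth)
    f1 = 2 * prec * rec / max(prec + rec, 1e-12)
    return f1, prec, rec


@pytest.fixture(scope="session")
def night():
    """A 40-min synthetic night at 27 degC with its analysis chain.

    Returns a dict with the recording, ground truth, preprocessed LFP,
    delta/beta series and segmented cycles — enough cycles (~25) for the
    phase and state statistics exercised across the suite.
    """
    cfg = GenConfig(duration_s=2400.0, lfp_rate_hz=1000.0, seed=11)
    rec, truth = generate_recording(cfg)
    sig = preprocess_lfp(LfpSignal(rec.lfp[0], rec.lfp_rate_hz))
    db = delta_beta_series(sig)
    cycles = segment_cycles(db)
    return {"cfg": cfg, "rec": rec, "truth": truth, "sig": sig, "db": db,
            "cycles": cycles}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
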