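import numpy as np
import pytest

import dynflux as dx


@pytest.fixture(scope="session")
def linear_run():
    """Noise-free simulation of the linear-feedback chain (default design)."""
    return dx.simulate_linear_feedback()


@pytest.fixture(scope="session")
def linear_slopes(linear_run):
    ts, _ = linear_run
    sm = dx.smooth_series(ts)
    return sm, dx.estimate_slopes(sm)


@pytest.fixture(scope="session")
def linear_inference(linear_slopes):
    """Bins, pairs and anchored v3 curve for the default system-A design."""
    sm, slopes = linear_slopes
    bins = dx.bin_fixed_variable(sm, slopes, "X1", "X2", "X2", 0.05)
    pairs_all = dx.extract_pairs(bins)
    pairs = dx.filter_pairs(pairs_all, 0.2)
    rel = dx.merge_pairs(pairs)
    curve = dx.anchor_curve(rel, "known_point", x0=1.0, v0=v3_truth(1.0))
    return bins, pairs_all, pairs, rel, curve


def v3_truth(x):
    """True Hill law of the linear system's v3 (V_max=5, K_M=2, h=3)."""
    x = np.asarray(x, dtype=float)
    out = 5.0 * x**3 / (8.0 + x**3)
    return out if out.ndim else float(out)


@pytest.fixture(scope="session")
def trehalose_run():
    return dx.simulate_trehalose_like()
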