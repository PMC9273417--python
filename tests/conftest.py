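import numpy as np
import pytest

from wbcseg.synthetic import SmearConfig, generate_smear


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_smear():
    """One deterministic 64×64 smear with mask and metadata."""
    cfg = SmearConfig(size=(64, 64), n_leukocytes=2, n_distractors=8,
                      leukocyte_axes=(5.0, 8.0), distractor_axes=(3.0, 5.0),
                      seed=7)
    return generate_smear(cfg)


def brute_force_conv_reflect(plane: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct O(H*W*K^2) convolution with symmetric (reflect-including-edge)
    boundary handling; the independent oracle for the surround blur."""
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2
    padded = np.pad(plane, ((rh, rh), (rw, rw)), mode="symmetric")
    h, w = plane.shape
    out = np.zeros_like(plane, dtype=np.float64)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    acc += kernel[a, b] * padded[i + a, j + b]
            out[i, j] = acc
    return out
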