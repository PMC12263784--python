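import os

# single-threaded BLAS keeps floating-point reduction order fixed, making
# seeded fits bit-reproducible (must be set before numpy initialises)
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from deeplfm.synthetic import SplitSpec, ToySystemSpec, make_split, simulate_toy
from deeplfm.training import Preprocessor


@pytest.fixture(scope="session")
def toy_frame():
    return simulate_toy(ToySystemSpec(seed=0))


@pytest.fixture(scope="session")
def toy_regression(toy_frame):
    """Standardised (X, Y, test_mask, preprocessor) for the toy target y2."""
    t = toy_frame["t"].to_numpy()[:, None]
    y = toy_frame["y2"].to_numpy()[:, None]
    mask = make_split(len(t), SplitSpec(mode="imputation", block_len=50, seed=3), 1)
    pre = Preprocessor().fit(t, y, ~mask)
    return pre.transform_x(t), pre.transform_y(y), mask, pre


def gradcheck(fn, arrays, eps=1e-6, rtol=1e-4):
    """Central finite-difference check of reverse-mode gradients."""
    from deeplfm._ad import parameter

    params = [parameter(a) for a in arrays]
    fn(*params).backward()
    for i, p in enumerate(params):
        num = np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p.data[idx]
            p.data[idx] = orig + eps
            f1 = fn(*params).data.sum()
            p.data[idx] = orig - eps
            f2 = fn(*params).data.sum()
            p.data[idx] = orig
            num[idx] = (f1 - f2) / (2 * eps)
        scale = max(1.0, np.abs(num).max())
        err = np.abs(num - p.grad).max() / scale
        assert err < rtol, f"gradient mismatch for argument {i}: {err:.2e}"
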