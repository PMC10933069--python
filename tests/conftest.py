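import numpy as np
import pytest

from mrxome.instruments import HarmonizedRecord, HarmonizedSet


def make_harmonized(
    rng: np.random.Generator,
    k: int,
    beta: float = 0.3,
    se_y_scale: float = 0.05,
) -> HarmonizedSet:
    """Random harmonized set with heterogeneous weights, exact-model outcome
    noise (by ~ N(beta*bx, se_y^2))."""
    bx = rng.uniform(0.05, 0.3, k) * rng.choice([-1, 1], k)
    se_x = rng.uniform(0.005, 0.02, k)
    se_y = se_y_scale * rng.uniform(0.5, 1.5, k)
    by = beta * bx + rng.normal(0, se_y)
    records = [
        HarmonizedRecord(
            variant_id=f"rs{i}",
            beta_exposure=float(bx[i]),
            se_exposure=float(se_x[i]),
            beta_outcome=float(by[i]),
            se_outcome=float(se_y[i]),
            pval_exposure=1e-9,
            pval_outcome=0.5,
        )
        for i in range(k)
    ]
    return HarmonizedSet("exp", "out", records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
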