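import numpy as np
import pytest

from mrlova import HarmonizedPanel


def synthetic_panel(
    m=30,
    n=10_000,
    tau=0.0,
    u=None,
    b_true=None,
    noise=True,
    seed=0,
):
    """Standardized summary panel drawn directly from the summary-level model.

    b_hat ~ b + N(0, 1/n), g_hat ~ tau*b + u + N(0, 1/n).  Bypasses
    individual-level simulation for fast unit tests.
    """
    rng = np.random.default_rng(seed)
    if b_true is None:
        b_true = rng.uniform(0.03, 0.12, size=m)
    b_true = np.asarray(b_true, dtype=float)
    m = len(b_true)
    u_true = np.zeros(m) if u is None else np.asarray(u, dtype=float)
    se = 1.0 / np.sqrt(n)
    eps_b = rng.normal(0.0, se, size=m) if noise else 0.0
    eps_g = rng.normal(0.0, se, size=m) if noise else 0.0
    return HarmonizedPanel(
        snp_id=np.array([f"rs{j+1}" for j in range(m)]),
        b_hat=b_true + eps_b,
        se_b=np.full(m, se),
        g_hat=tau * b_true + u_true + eps_g,
        se_g=np.full(m, se),
        n_exp=n,
        n_out=n,
    )


@pytest.fixture
def panel_factory():
    return synthetic_panel
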