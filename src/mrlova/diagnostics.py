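"""Pleiotropy diagnostics and reference estimators.

Three checks accompany a fitted causal effect:

* a permutation test of the causal estimate, breaking the pairing
  between exposure effects and outcome effects;
* a one-sample t-test of the mean direct effect (directional
  horizontal pleiotropy biases naive MR when mean(u) != 0);
* a Pearson correlation test of cor(u, b) — a nonzero correlation
  violates the InSIDE assumption (Instrument Strength Independent of
  Direct Effect), typically through a genetic confounder.

Both pleiotropy tests use the direct effects u_hat evaluated at the
converged causal estimate over ALL relevance-passing instruments, not
just the selected ones: excluded instruments carry precisely the
pleiotropy signal the tests look for.

Simple IVW and MR-Egger fits are included as internal baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .em import CausalResult, EMState, LDMatrix, fit
from .summary_io import HarmonizedPanel

logger = logging.getLogger(__name__)


@dataclass
class DiagnosticsResult:
    """Directional-pleiotropy and InSIDE-violation test results."""

    dir_pleio_t: float
    dir_pleio_df: int
    dir_pleio_p: float
    inside_r: float
    inside_p: float
    n_snps_used: int

    def to_dict(self) -> dict:
        return {
            "directional_pleiotropy": {
                "t": self.dir_pleio_t,
                "df": self.dir_pleio_df,
                "p": self.dir_pleio_p,
            },
            "inside_violation": {"r": self.inside_r, "p": self.inside_p},
            "n_snps_used": self.n_snps_used,
        }


def permutation_test(
    panel: HarmonizedPanel,
    observed: CausalResult,
    n_perm: int = 1000,
    seed: int | None = None,
    **fit_kwargs,
) -> float:
    """Empirical two-sided p-value for tau_hat under label shuffling.

    Each permutation jointly shuffles the (g_hat, se_g) pairs — the
    latent-outcome effects and standard errors at the tau = 0
    initialization — against b_hat, re-runs the complete EM fit (so
    instrument-selection uncertainty is propagated), and records the
    permuted estimate.  Returns

        p = (1 + #{|tau_perm| >= |tau_obs|}) / (n_perm + 1)

    which can never be exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    m = len(panel)
    exceed = 0
    n_ok = 0
    for _ in range(n_perm):
        order = rng.permutation(m)
        shuffled = HarmonizedPanel(
            snp_id=panel.snp_id,
            b_hat=panel.b_hat,
            se_b=panel.se_b,
            g_hat=panel.g_hat[order],
            se_g=panel.se_g[order],
            n_exp=panel.n_exp,
            n_out=panel.n_out,
        )
        try:
            res = fit(shuffled, **fit_kwargs)
        except Exception as exc:  # selection may collapse on a shuffled panel
            logger.warning("permutation replicate failed (%s); skipped", exc)
            continue
        n_ok += 1
        if abs(res.tau_hat) >= abs(observed.tau_hat):
            exceed += 1
    if n_ok == 0:
        raise RuntimeError("all permutation replicates failed")
    return (1.0 + exceed) / (n_ok + 1.0)


def directional_pleiotropy_test(u_hat) -> tuple[float, int, float]:
    """One-sample t-test of mean(u_hat) against zero.

    A significant result indicates directional horizontal pleiotropy.
    Returns (t, df, two-sided p).
    """
    u_hat = np.asarray(u_hat, dtype=float)
    if len(u_hat) < 2:
        raise ValueError("need at least 2 instruments for the t-test")
    if np.ptp(u_hat) == 0:
        raise ValueError("direct effects have zero variance; t-test undefined")
    t, p = stats.ttest_1samp(u_hat, 0.0)
    return float(t), len(u_hat) - 1, float(p)


def inside_test(u_hat, b_hat) -> tuple[float, float]:
    """Pearson correlation test of cor(u, b) against zero.

    A significant correlation between direct effects and instrument
    strengths violates the InSIDE assumption.  Returns (r, two-sided p)
    from the t transform with m - 2 degrees of freedom.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    b_hat = np.asarray(b_hat, dtype=float)
    if len(u_hat) != len(b_hat):
        raise ValueError("u_hat and b_hat must have equal length")
    if len(u_hat) < 3:
        raise ValueError("need at least 3 instruments for the correlation test")
    if np.ptp(u_hat) == 0 or np.ptp(b_hat) == 0:
        raise ValueError("constant input; correlation undefined")
    r, p = stats.pearsonr(u_hat, b_hat)
    return float(r), float(p)


def diagnose(panel: HarmonizedPanel, result: CausalResult) -> DiagnosticsResult:
    """Run both pleiotropy tests on a fitted result's direct effects."""
    state: EMState = result.state
    if state is None:
        raise ValueError("result carries no EM state; refit before diagnosing")
    t, df, p_t = directional_pleiotropy_test(state.u_hat)
    r, p_r = inside_test(state.u_hat, panel.b_hat)
    return DiagnosticsResult(
        dir_pleio_t=t, dir_pleio_df=df, dir_pleio_p=p_t,
        inside_r=r, inside_p=p_r, n_snps_used=len(state.u_hat),
    )


# ---------------------------------------------------------------------------
# Internal baselines
# ---------------------------------------------------------------------------

def baseline_ivw(panel: HarmonizedPanel) -> CausalResult:
    """Fixed-effect inverse-variance-weighted estimate.

    Precision-weighted regression of outcome effects on exposure effects
    through the origin; with a single instrument this reduces to the Wald
    ratio g_hat / b_hat.
    """
    if len(panel) < 1:
        raise ValueError("IVW needs at least 1 SNP")
    w = 1.0 / panel.se_g**2
    denom = float(np.sum(w * panel.b_hat**2))
    tau = float(np.sum(w * panel.g_hat * panel.b_hat) / denom)
    se = float(1.0 / np.sqrt(denom))
    p = float(2.0 * stats.norm.sf(abs(tau) / se))
    return CausalResult(
        tau_hat=tau, se_tau=se, pvalue=p, n_iter=0,
        n_selected=len(panel), selected_ids=list(panel.snp_id),
        converged=True, trace=[(0, tau)], method="ivw",
    )


@dataclass
class EggerResult:
    """MR-Egger fit: slope plus the intercept test for directional pleiotropy."""

    result: CausalResult
    intercept: float
    intercept_se: float
    intercept_p: float


def baseline_egger(panel: HarmonizedPanel) -> EggerResult:
    """MR-Egger: precision-weighted regression with a free intercept."""
    if len(panel) < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    X = sm.add_constant(panel.b_hat)
    model = sm.WLS(panel.g_hat, X, weights=1.0 / panel.se_g**2).fit()
    icpt, slope = model.params
    icpt_se, slope_se = model.bse
    slope_p = float(2.0 * stats.norm.sf(abs(slope) / slope_se))
    icpt_p = float(2.0 * stats.norm.sf(abs(icpt) / icpt_se))
    res = CausalResult(
        tau_hat=float(slope), se_tau=float(slope_se), pvalue=slope_p,
        n_iter=0, n_selected=len(panel), selected_ids=list(panel.snp_id),
        converged=True, trace=[(0, float(slope))], method="egger",
    )
    return EggerResult(
        result=res, intercept=float(icpt),
        intercept_se=float(icpt_se), intercept_p=icpt_p,
    )
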