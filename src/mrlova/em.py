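"""MR-LOVA: causal-effect estimation via a latent outcome variable.

The model behind the method is

    c = X b + eps            (exposure)
    y = c tau + X u + e      (outcome)

where ``b`` are instrument strengths, ``u`` direct (horizontally
pleiotropic) SNP effects on the outcome, and ``tau`` the causal effect of
interest.  Subtracting the causal pathway gives a latent outcome

    upsilon = y - c tau = X u + e

whose GWAS isolates the direct effects: a valid instrument is one whose
effect on upsilon is null.  Since tau is unknown, a stochastic EM loop
alternates between

  E-step   impute the latent-outcome effects  u_hat_j = g_hat_j - tau b_hat_j
           with sampling variance  var(g_hat_j) + (tau^2 - 2 tau cov(y,c))/n
  select   I_j = 1 iff u_hat_j is not significant on the latent outcome
           (p > p_out, exclusion restriction) and b_hat_j is significant
           on the exposure (p < p_exp, relevance)
  M-step   inverse-variance-weighted regression of u_hat on b_hat over the
           selected set; since u_hat is already residualized on the current
           tau, the fitted slope is the increment tau^(t+1) = tau^(t) + delta

until the update falls below tolerance.  All quantities are on the
standardized scale produced by :mod:`mrlova.summary_io`, where
var(g_hat_j) = 1/n_out.

Correlated instruments can be accommodated by rotating u_hat through the
inverse of an LD correlation matrix estimated from a reference panel
(:func:`ld_adjust`).  An individual-level path (:func:`fit_individual`)
forms the latent outcome explicitly per individual.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .summary_io import HarmonizedPanel, exposure_pvalues

logger = logging.getLogger(__name__)

#: lower bound applied to sampling variances of u_hat
VAR_U_FLOOR = 1e-12
#: |cov(y,c)| is clipped below 1 so that var(upsilon) = 1 + tau^2 - 2 tau cov
#: stays positive for every tau
COV_YC_BOUND = 0.999
#: ridge added to an LD matrix whose smallest eigenvalue is < RIDGE_EIG_TOL
RIDGE = 1e-3
RIDGE_EIG_TOL = 1e-6


class NoValidInstrumentsError(RuntimeError):
    """Raised when instrument selection is empty at convergence."""

    def __init__(self, message: str, state: "EMState | None" = None):
        super().__init__(message)
        self.state = state


@dataclass
class EMState:
    """Snapshot of the EM at one iteration."""

    tau: float
    u_hat: np.ndarray        # direct SNP effects on the outcome
    var_u: np.ndarray        # their sampling variances
    include: np.ndarray      # inclusion indicators I_j (bool)
    iteration: int
    converged: bool


@dataclass
class CausalResult:
    """Final causal-effect estimate with its instrument selection."""

    tau_hat: float
    se_tau: float
    pvalue: float
    n_iter: int
    n_selected: int
    selected_ids: list
    converged: bool
    trace: list                  # (iteration, tau) pairs
    state: EMState | None = None
    perm_pvalue: float | None = None
    method: str = "mr_lova"

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "tau_hat": self.tau_hat,
            "se_tau": self.se_tau,
            "pvalue": self.pvalue,
            "n_iter": self.n_iter,
            "n_selected": self.n_selected,
            "selected_ids": list(map(str, self.selected_ids)),
            "converged": self.converged,
            "trace": [[int(i), float(t)] for i, t in self.trace],
        }
        if self.perm_pvalue is not None:
            d["perm_pvalue"] = self.perm_pvalue
        return d


@dataclass(frozen=True)
class LDMatrix:
    """Instrument-by-instrument correlation matrix from a reference panel."""

    omega: np.ndarray
    snp_ids: tuple

    def __post_init__(self):
        om = np.asarray(self.omega, dtype=float)
        if om.ndim != 2 or om.shape[0] != om.shape[1]:
            raise ValueError("LD matrix must be square")
        if om.shape[0] != len(self.snp_ids):
            raise ValueError("LD matrix size does not match snp_ids")
        if not np.allclose(om, om.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(om), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        if np.any(np.abs(om) > 1.0 + 1e-8):
            raise ValueError("LD matrix entries must lie in [-1, 1]")
        object.__setattr__(self, "omega", om)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))

    @classmethod
    def from_files(cls, matrix_path, snp_path) -> "LDMatrix":
        """Load a whitespace-delimited square matrix plus a sidecar id list."""
        om = np.loadtxt(matrix_path)
        with open(snp_path) as fh:
            ids = [line.strip() for line in fh if line.strip()]
        return cls(om, tuple(ids))

    def aligned_to(self, snp_ids) -> np.ndarray:
        """Return the correlation sub-matrix in the panel's SNP order."""
        index = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            order = [index[s] for s in snp_ids]
        except KeyError as exc:
            raise ValueError(f"SNP {exc.args[0]!r} missing from LD matrix") from exc
        return self.omega[np.ix_(order, order)]


@dataclass
class CohortData:
    """Individual-level data for one cohort: dosages, exposure, outcome."""

    X: np.ndarray
    c: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X)
        self.c = np.asarray(self.c, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.X.shape[0]
        if len(self.c) != n or len(self.y) != n:
            raise ValueError("phenotype length does not match genotype rows")


# ---------------------------------------------------------------------------
# E-step and M-step primitives
# ---------------------------------------------------------------------------

def estimate_cov_yc(panel: HarmonizedPanel) -> float:
    """Approximate cov(y, c) by the genetic covariance sum_j g_hat_j b_hat_j.

    For independent standardized SNPs the phenotypic covariance between
    outcome and exposure is approximated by the inner product of their
    standardized effect vectors over the instrument panel.  The value is
    clipped to (-1, 1) so that var(upsilon) = 1 + tau^2 - 2 tau cov stays
    positive for every tau.
    """
    if len(panel) < 2:
        raise ValueError("need at least 2 SNPs to approximate cov(y, c)")
    cov = float(np.dot(panel.g_hat, panel.b_hat))
    return float(np.clip(cov, -COV_YC_BOUND, COV_YC_BOUND))


def e_step(panel: HarmonizedPanel, tau: float, cov_yc: float):
    """Impute latent-outcome effects and their sampling variances.

    u_hat_j = g_hat_j - tau b_hat_j
    var(u_hat_j) = var(g_hat_j) + (tau^2 - 2 tau cov(y,c)) / n_out
    """
    u_hat = panel.g_hat - tau * panel.b_hat
    var_u = panel.se_g**2 + (tau**2 - 2.0 * tau * cov_yc) / panel.n_out
    n_floored = int(np.sum(var_u < VAR_U_FLOOR))
    if n_floored:
        if n_floored == len(var_u):
            raise ValueError(
                f"all u_hat variances non-positive at tau={tau:g}, cov_yc={cov_yc:g}"
            )
        logger.warning("e_step: floored %d non-positive u_hat variances", n_floored)
        var_u = np.maximum(var_u, VAR_U_FLOOR)
    return u_hat, var_u


def inclusion_indicator(
    u_hat, var_u, b_hat, se_b, p_out: float = 0.05, p_exp: float = 5e-8
) -> np.ndarray:
    """Select instruments satisfying exclusion restriction and relevance.

    I_j = 1 iff the latent-outcome effect u_hat_j is NOT significant
    (two-sided normal p > p_out) and the exposure effect b_hat_j IS
    significant (p < p_exp).
    """
    p_u = 2.0 * stats.norm.sf(np.abs(np.asarray(u_hat) / np.sqrt(var_u)))
    p_b = 2.0 * stats.norm.sf(np.abs(np.asarray(b_hat) / np.asarray(se_b)))
    return (p_u > p_out) & (p_b < p_exp)


def m_step_ivw(u_hat, var_u, b_hat, include) -> float:
    """IVW slope of u_hat on b_hat over the selected instruments.

    Because u_hat is residualized on the current tau, the returned slope
    is the increment delta; the caller updates tau <- tau + delta.
    """
    include = np.asarray(include, dtype=bool)
    if include.sum() < 1:
        raise NoValidInstrumentsError("no instruments selected for the M-step")
    w = 1.0 / np.asarray(var_u)[include]
    b = np.asarray(b_hat)[include]
    u = np.asarray(u_hat)[include]
    denom = float(np.sum(w * b * b))
    if denom <= 0:
        raise NoValidInstrumentsError("degenerate M-step: sum of weighted b^2 is zero")
    return float(np.sum(w * u * b) / denom)


def ld_adjust(u_hat, var_upsilon: float, omega: np.ndarray, n_out: int):
    """Rotate marginal latent-outcome effects through the LD matrix.

    For correlated instruments the joint (multiple-regression) direct
    effects are Omega^{-1} u_hat with sampling variances
    diag[(n Omega)^{-1}] (var(upsilon) - R^2) where
    R^2 = (Omega^{-1} u_hat)' Omega (Omega^{-1} u_hat) = u_hat' Omega^{-1} u_hat.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (len(u_hat), len(u_hat)):
        raise ValueError("LD matrix dimensions do not match the panel")
    eigmin = float(np.linalg.eigvalsh(omega).min())
    if eigmin < RIDGE_EIG_TOL:
        logger.warning(
            "ld_adjust: smallest eigenvalue %.3g < %g; adding ridge %g",
            eigmin, RIDGE_EIG_TOL, RIDGE,
        )
        omega = omega + RIDGE * np.eye(len(u_hat))
        if float(np.linalg.eigvalsh(omega).min()) <= 0:
            raise np.linalg.LinAlgError("LD matrix singular even after ridge")
    omega_inv = np.linalg.inv(omega)
    u_adj = omega_inv @ u_hat
    r2 = float(u_hat @ u_adj)
    if r2 >= var_upsilon:
        warnings.warn(
            f"LD-adjusted R^2 = {r2:.4g} >= var(upsilon) = {var_upsilon:.4g}; capping",
            RuntimeWarning,
            stacklevel=2,
        )
        r2 = 0.999 * var_upsilon
    var_adj = np.diag(omega_inv) / n_out * (var_upsilon - r2)
    var_adj = np.maximum(var_adj, VAR_U_FLOOR)
    return u_adj, var_adj


# ---------------------------------------------------------------------------
# Full fits
# ---------------------------------------------------------------------------

def _em_loop(panel, b_pvalues, tau0, tol, max_iter, p_out, p_exp, omega):
    """Shared EM iteration over a standardized panel."""
    cov_yc = estimate_cov_yc(panel)
    relevance = b_pvalues < p_exp
    if not relevance.any():
        raise NoValidInstrumentsError(
            f"no SNP passes the exposure relevance threshold p < {p_exp:g}"
        )
    tau = float(tau0)
    trace = [(0, tau)]
    converged = False
    u_hat = var_u = include = None
    it = 0
    for it in range(1, max_iter + 1):
        u_hat, var_u = _latent_effects(panel, tau, cov_yc, omega)
        p_u = 2.0 * stats.norm.sf(np.abs(u_hat / np.sqrt(var_u)))
        include = (p_u > p_out) & relevance
        if not include.any():
            logger.warning(
                "iteration %d: empty selection; falling back to relevance-only set", it
            )
            include = relevance.copy()
        delta = m_step_ivw(u_hat, var_u, panel.b_hat, include)
        tau += delta
        trace.append((it, tau))
        if abs(delta) < tol:
            converged = True
            break
    # final selection evaluated at the converged tau
    u_hat, var_u = _latent_effects(panel, tau, cov_yc, omega)
    p_u = 2.0 * stats.norm.sf(np.abs(u_hat / np.sqrt(var_u)))
    include = (p_u > p_out) & relevance
    state = EMState(tau=tau, u_hat=u_hat, var_u=var_u, include=include,
                    iteration=it, converged=converged)
    if not include.any():
        raise NoValidInstrumentsError(
            "no valid instruments at convergence", state=state
        )
    return state, trace


def _latent_effects(panel, tau, cov_yc, omega):
    u_hat, var_u = e_step(panel, tau, cov_yc)
    if omega is not None:
        var_upsilon = 1.0 + tau**2 - 2.0 * tau * cov_yc
        u_hat, var_u = ld_adjust(u_hat, var_upsilon, omega, panel.n_out)
    return u_hat, var_u


def _finalize(panel, state, trace, method):
    se_tau = float(
        1.0 / np.sqrt(np.sum(panel.b_hat[state.include] ** 2 / state.var_u[state.include]))
    )
    pvalue = float(2.0 * stats.norm.sf(abs(state.tau) / se_tau))
    selected = list(np.asarray(panel.snp_id)[state.include])
    if not state.converged:
        logger.warning("EM did not converge within %d iterations", state.iteration)
    return CausalResult(
        tau_hat=state.tau,
        se_tau=se_tau,
        pvalue=pvalue,
        n_iter=state.iteration,
        n_selected=int(state.include.sum()),
        selected_ids=selected,
        converged=state.converged,
        trace=trace,
        state=state,
        method=method,
    )


def fit(
    panel: HarmonizedPanel,
    tau0: float = 0.0,
    tol: float = 1e-6,
    max_iter: int = 100,
    p_out: float = 0.05,
    p_exp: float = 5e-8,
    ld: LDMatrix | None = None,
) -> CausalResult:
    """Run the MR-LOVA EM on a standardized summary panel.

    Parameters
    ----------
    panel
        Harmonized, standardized exposure/outcome effects (normally
        already restricted to exposure-significant SNPs upstream).
    tau0
        Initial causal effect; 0 starts from "no causal effect", which
        guards against converging onto spurious signal.
    tol, max_iter
        Stop when |tau update| < tol, or flag ``converged=False`` after
        ``max_iter`` iterations (not an exception).
    p_out, p_exp
        Inclusion-rule thresholds: latent-outcome p-value above ``p_out``
        (exclusion restriction) and exposure p-value below ``p_exp``
        (relevance).
    ld
        Optional LD correlation matrix; when given, latent-outcome effects
        are rotated through its inverse each iteration.
    """
    omega = ld.aligned_to(panel.snp_id) if ld is not None else None
    b_pvalues = exposure_pvalues(panel)
    state, trace = _em_loop(panel, b_pvalues, tau0, tol, max_iter, p_out, p_exp, omega)
    name = "mr_lova_ref" if ld is not None else "mr_lova"
    return _finalize(panel, state, trace, name)


def fit_individual(
    exposure_cohort: CohortData,
    outcome_cohort: CohortData,
    tau0: float = 0.0,
    tol: float = 1e-6,
    max_iter: int = 100,
    p_out: float = 0.05,
    p_exp: float = 5e-8,
    snp_ids=None,
) -> CausalResult:
    """MR-LOVA on individual-level data.

    The exposure cohort provides the instrument-strength GWAS; in the
    outcome cohort the latent outcome is formed per individual each
    iteration as upsilon = y - c_hat tau, with c_hat the genetic
    prediction X b_hat of the exposure (two-sample design: the exposure
    itself is unobserved in the outcome cohort).  When both arguments are
    the same object (one-sample design) the observed exposure is used
    directly.  Genotypes and phenotypes are standardized within cohort;
    constant genotype columns are dropped with a warning.
    """
    X1 = np.asarray(exposure_cohort.X, dtype=float)
    X2 = np.asarray(outcome_cohort.X, dtype=float)
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("cohorts must share the same instruments")
    m = X1.shape[1]
    ids = np.asarray(snp_ids if snp_ids is not None else [f"snp{j+1}" for j in range(m)])

    sd1, sd2 = X1.std(axis=0), X2.std(axis=0)
    keep = (sd1 > 0) & (sd2 > 0)
    if not keep.all():
        logger.warning("dropping %d constant genotype columns", int((~keep).sum()))
        X1, X2, ids = X1[:, keep], X2[:, keep], ids[keep]
    n1, n2 = X1.shape[0], X2.shape[0]

    Z1 = (X1 - X1.mean(axis=0)) / X1.std(axis=0)
    Z2 = (X2 - X2.mean(axis=0)) / X2.std(axis=0)
    c1 = _zscore(exposure_cohort.c)
    y2 = _zscore(outcome_cohort.y)

    # exposure GWAS on standardized data: slope = correlation
    b_hat = Z1.T @ c1 / n1
    se_b = np.sqrt(np.maximum(1.0 - b_hat**2, VAR_U_FLOOR) / (n1 - 2))
    b_pvalues = 2.0 * stats.norm.sf(np.abs(b_hat / se_b))
    relevance = b_pvalues < p_exp
    if not relevance.any():
        raise NoValidInstrumentsError(
            f"no SNP passes the exposure relevance threshold p < {p_exp:g}"
        )

    one_sample = exposure_cohort is outcome_cohort
    c_pred = _zscore(outcome_cohort.c) if one_sample else Z2 @ b_hat

    tau = float(tau0)
    trace = [(0, tau)]
    converged = False
    it = 0

    def latent_gwas(tau_val):
        upsilon = y2 - tau_val * c_pred
        u = Z2.T @ upsilon / n2
        var_ups = float(np.var(upsilon))
        var_u = np.maximum(var_ups - u**2, VAR_U_FLOOR) / (n2 - 2)
        return u, var_u

    for it in range(1, max_iter + 1):
        u_hat, var_u = latent_gwas(tau)
        p_u = 2.0 * stats.norm.sf(np.abs(u_hat / np.sqrt(var_u)))
        include = (p_u > p_out) & relevance
        if not include.any():
            logger.warning(
                "iteration %d: empty selection; falling back to relevance-only set", it
            )
            include = relevance.copy()
        delta = m_step_ivw(u_hat, var_u, b_hat, include)
        tau += delta
        trace.append((it, tau))
        if abs(delta) < tol:
            converged = True
            break

    u_hat, var_u = latent_gwas(tau)
    p_u = 2.0 * stats.norm.sf(np.abs(u_hat / np.sqrt(var_u)))
    include = (p_u > p_out) & relevance
    state = EMState(tau=tau, u_hat=u_hat, var_u=var_u, include=include,
                    iteration=it, converged=converged)
    if not include.any():
        raise NoValidInstrumentsError("no valid instruments at convergence", state=state)
    se_tau = float(1.0 / np.sqrt(np.sum(b_hat[include] ** 2 / var_u[include])))
    pvalue = float(2.0 * stats.norm.sf(abs(tau) / se_tau))
    return CausalResult(
        tau_hat=tau,
        se_tau=se_tau,
        pvalue=pvalue,
        n_iter=it,
        n_selected=int(include.sum()),
        selected_ids=list(ids[include]),
        converged=converged,
        trace=trace,
        state=state,
        method="mr_lova_ind",
    )


def _zscore(v):
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("constant phenotype")
    return (v - v.mean()) / sd
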