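"""Reading, harmonizing and standardizing GWAS summary statistics.

This module turns two per-SNP association tables (exposure and outcome)
into the aligned, standardized panel the EM engine works on.  Effects are
put on the "standardized genotype, standardized phenotype" scale on which
a marginal effect estimate has sampling variance 1/n: the standardized
effect is z/sqrt(n) with z = beta/se, and its standard error is 1/sqrt(n).
This ignores the O(z^2/n) correction, which is negligible when a single
variant explains a tiny fraction of trait variance, as in GWAS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: default column names of common GWAS summary-statistic exports
DEFAULT_COLUMNS = {
    "snp_id": "SNP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

_VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class ConfigurationError(ValueError):
    """A required column or option is missing or invalid."""


class HarmonizationError(ValueError):
    """The exposure and outcome tables cannot be aligned."""


@dataclass
class SummaryTable:
    """One GWAS summary-statistic table with canonical column names.

    ``data`` holds columns snp_id, effect_allele, other_allele, beta, se,
    pvalue, n.  Invariants (unique SNP ids, positive se, distinct alleles)
    are enforced at construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["snp_id", "effect_allele", "other_allele", "beta", "se", "n"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"summary table lacks columns: {missing}")
        df = self.data
        if df["snp_id"].duplicated().any():
            dups = df.loc[df["snp_id"].duplicated(), "snp_id"].head(3).tolist()
            raise ConfigurationError(f"duplicated snp_id values (e.g. {dups})")
        if (df["se"] <= 0).any():
            raise ConfigurationError("all standard errors must be strictly positive")
        if (df["effect_allele"] == df["other_allele"]).any():
            raise ConfigurationError("effect and other allele identical for some SNPs")
        if "pvalue" not in df.columns:
            z = df["beta"] / df["se"]
            self.data = df.assign(pvalue=2.0 * stats.norm.sf(np.abs(z)))

    def __len__(self) -> int:
        return len(self.data)

    def to_tsv(self, path, column_map: dict | None = None) -> None:
        """Write the table in the dialect :func:`read_summary` reads."""
        colmap = dict(DEFAULT_COLUMNS)
        if column_map:
            colmap.update(column_map)
        out = self.data.rename(columns={k: v for k, v in colmap.items()
                                        if k in self.data.columns})
        out.to_csv(path, sep="\t", index=False)


def read_summary(
    path,
    column_map: dict | None = None,
    n: int | None = None,
) -> SummaryTable:
    """Read a whitespace/TAB-delimited GWAS summary-statistics file.

    Parameters
    ----------
    path
        Text file with one header row.
    column_map
        Mapping from canonical field names (keys of ``DEFAULT_COLUMNS``)
        to the column names used in the file; unspecified fields fall back
        to the defaults (SNP, A1, A2, BETA, SE, P, N).
    n
        Global sample size, used when the file has no per-SNP N column.

    Rows with missing or non-numeric beta/se are dropped with a logged
    count.  A missing mandatory column raises :class:`ConfigurationError`.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown column_map keys: {sorted(unknown)}")
        colmap.update(column_map)

    raw = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    mandatory = ["snp_id", "effect_allele", "other_allele", "beta", "se"]
    for key in mandatory:
        if colmap[key] not in raw.columns:
            raise ConfigurationError(
                f"column {colmap[key]!r} (field {key}) missing from {path}"
            )

    df = pd.DataFrame(
        {
            "snp_id": raw[colmap["snp_id"]].astype(str),
            "effect_allele": raw[colmap["effect_allele"]].str.upper(),
            "other_allele": raw[colmap["other_allele"]].str.upper(),
            "beta": pd.to_numeric(raw[colmap["beta"]], errors="coerce"),
            "se": pd.to_numeric(raw[colmap["se"]], errors="coerce"),
        }
    )
    if colmap["pvalue"] in raw.columns:
        df["pvalue"] = pd.to_numeric(raw[colmap["pvalue"]], errors="coerce")
    if colmap["n"] in raw.columns:
        df["n"] = pd.to_numeric(raw[colmap["n"]], errors="coerce")
    elif n is not None:
        df["n"] = n
    else:
        raise ConfigurationError(
            f"no sample-size column {colmap['n']!r} in {path} and no global n given"
        )

    bad = df["beta"].isna() | df["se"].isna() | (df["se"] <= 0) | df["n"].isna()
    if bad.any():
        logger.warning("%s: dropped %d rows with missing/invalid beta, se or n",
                       path, int(bad.sum()))
        df = df.loc[~bad]
    df = df.reset_index(drop=True)
    return SummaryTable(df)


@dataclass(frozen=True)
class HarmonizedPanel:
    """Exposure/outcome effects aligned on a shared effect allele.

    After :func:`standardize_effects` the effects are on the standardized
    scale, where ``se_b = 1/sqrt(n_exp)`` and ``se_g = 1/sqrt(n_out)``
    exactly.  ``b_hat`` are exposure effects, ``g_hat`` outcome effects.
    """

    snp_id: np.ndarray
    b_hat: np.ndarray
    se_b: np.ndarray
    g_hat: np.ndarray
    se_g: np.ndarray
    n_exp: int
    n_out: int

    def __post_init__(self) -> None:
        m = len(self.snp_id)
        for name in ("b_hat", "se_b", "g_hat", "se_g"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} length != number of SNPs")
        if len(set(self.snp_id)) != m:
            raise ValueError("duplicated snp_id in panel")
        if np.any(self.se_b <= 0) or np.any(self.se_g <= 0):
            raise ValueError("standard errors must be strictly positive")

    def __len__(self) -> int:
        return len(self.snp_id)

    def subset(self, mask: np.ndarray) -> "HarmonizedPanel":
        return HarmonizedPanel(
            snp_id=np.asarray(self.snp_id)[mask],
            b_hat=self.b_hat[mask],
            se_b=self.se_b[mask],
            g_hat=self.g_hat[mask],
            se_g=self.se_g[mask],
            n_exp=self.n_exp,
            n_out=self.n_out,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "b_hat": self.b_hat,
                "se_b": self.se_b,
                "g_hat": self.g_hat,
                "se_g": self.se_g,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    drop_palindromic: bool = False,
) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele.

    Returns a merged per-SNP table (columns ``*_exp`` / ``*_out``) on the
    original per-allele scale; :func:`make_panel` standardizes it.  SNPs
    present in only one table, or with incompatible allele pairs, are
    dropped; outcome betas are sign-flipped where the outcome's effect and
    other alleles are swapped relative to the exposure.  A/T and C/G
    (palindromic) SNPs are optionally removed, since their strand cannot
    be resolved from allele codes alone.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise HarmonizationError("empty summary table")
    merged = exposure.data.merge(
        outcome.data, on="snp_id", suffixes=("_exp", "_out"), how="inner"
    )
    n_common = len(merged)
    if n_common == 0:
        raise HarmonizationError("no SNPs shared between exposure and outcome tables")

    same = (merged["effect_allele_exp"] == merged["effect_allele_out"]) & (
        merged["other_allele_exp"] == merged["other_allele_out"]
    )
    swapped = (merged["effect_allele_exp"] == merged["other_allele_out"]) & (
        merged["other_allele_exp"] == merged["effect_allele_out"]
    )
    merged.loc[swapped, "beta_out"] = -merged.loc[swapped, "beta_out"]
    keep = same | swapped
    n_flipped = int(swapped.sum())
    n_mismatch = int((~keep).sum())
    merged = merged.loc[keep]

    n_palin = 0
    if drop_palindromic:
        palin = [
            (ea, oa) in _PALINDROMIC
            for ea, oa in zip(merged["effect_allele_exp"], merged["other_allele_exp"])
        ]
        palin = np.asarray(palin, dtype=bool)
        n_palin = int(palin.sum())
        merged = merged.loc[~palin]

    logger.info(
        "harmonize: %d shared SNPs, %d outcome betas flipped, "
        "%d allele-mismatched dropped, %d palindromic dropped, %d kept",
        n_common, n_flipped, n_mismatch, n_palin, len(merged),
    )
    if len(merged) == 0:
        raise HarmonizationError("no SNPs left after allele harmonization")
    return merged.reset_index(drop=True)


def standardize_effects(beta, se, n):
    """Convert per-allele effects to the standardized scale.

    Returns ``(z/sqrt(n), 1/sqrt(n))`` with ``z = beta/se``: the effect of
    a standardized genotype on a standardized trait, whose sampling
    variance is 1/n.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 1):
        raise ValueError("sample size must exceed 1 for standardization")
    if np.any(se <= 0):
        raise ValueError("standard errors must be strictly positive")
    z = beta / se
    return z / np.sqrt(n), 1.0 / np.sqrt(n)


def make_panel(
    exposure: SummaryTable,
    outcome: SummaryTable,
    drop_palindromic: bool = False,
) -> HarmonizedPanel:
    """Harmonize two summary tables and standardize them into a panel."""
    merged = harmonize(exposure, outcome, drop_palindromic=drop_palindromic)
    n_exp = int(round(float(np.median(merged["n_exp"]))))
    n_out = int(round(float(np.median(merged["n_out"]))))
    b_hat, _ = standardize_effects(merged["beta_exp"], merged["se_exp"], merged["n_exp"])
    g_hat, _ = standardize_effects(merged["beta_out"], merged["se_out"], merged["n_out"])
    m = len(merged)
    return HarmonizedPanel(
        snp_id=merged["snp_id"].to_numpy(),
        b_hat=b_hat,
        se_b=np.full(m, 1.0 / np.sqrt(n_exp)),
        g_hat=g_hat,
        se_g=np.full(m, 1.0 / np.sqrt(n_out)),
        n_exp=n_exp,
        n_out=n_out,
    )


def relevance_filter(panel: HarmonizedPanel, p_exposure: float = 5e-8) -> HarmonizedPanel:
    """Keep SNPs robustly associated with the exposure (relevance assumption).

    Retains SNPs whose two-sided normal p-value for the exposure effect is
    below ``p_exposure``; order preserved.  Raises if nothing survives.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    p = exposure_pvalues(panel)
    mask = p < p_exposure
    n_kept = int(mask.sum())
    logger.info("relevance_filter: %d/%d SNPs pass p < %g", n_kept, len(panel), p_exposure)
    if n_kept == 0:
        raise ValueError(
            f"no SNP passes the exposure relevance threshold p < {p_exposure:g}"
        )
    if n_kept == len(panel):
        return panel
    return panel.subset(mask)


def exposure_pvalues(panel: HarmonizedPanel) -> np.ndarray:
    """Two-sided normal p-values of the standardized exposure effects."""
    z = panel.b_hat / panel.se_b
    return 2.0 * stats.norm.sf(np.abs(z))
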