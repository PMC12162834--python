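"""Negative-binomial differential test for count features.

The same machinery serves ATAC-seq consensus regions and RNA-seq genes:
median-of-ratios size factors, a per-feature method-of-moments dispersion
moderated toward the across-feature trend, and a Wald test on the log2 fold
change with a t reference whose degrees of freedom include the moderation
prior. Unmoderated small-replicate Wald tests are either anticonservative
(normal reference) or underpowered (t reference with 1-4 residual df); the
moderation is the standard empirical-Bayes remedy and keeps the nominal
type-I error at realistic replicate numbers.

Counts are modeled NB with variance mu + alpha * mu^2 (alpha = dispersion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "ComparisonSpec",
    "CONDITIONS",
    "estimate_size_factors",
    "nb_wald_test",
    "call_significant",
    "bh_adjust",
]

CONDITIONS = ("D2_soft", "D2_stiff", "D4_soft", "D4_stiff")

#: pseudo-count added to group means in the log2 fold change
LOG2FC_PSEUDOCOUNT = 0.5
#: lower floor for the dispersion estimate
DISPERSION_FLOOR = 1e-8
#: prior degrees of freedom for dispersion moderation
DISPERSION_PRIOR_DF = 10.0


class CountMatrix:
    """Non-negative integer counts, features x samples, with sample metadata.

    ``table`` is a features x samples DataFrame; ``samples`` a DataFrame
    indexed by sample_id with at least (assay, stiffness, day, replicate).
    """

    def __init__(self, table: pd.DataFrame, samples: pd.DataFrame):
        if table.index.has_duplicates:
            raise ValueError("feature ids must be unique")
        if (table.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(table.columns) - set(samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        self.table = table
        self.samples = samples.loc[list(table.columns)].copy()
        if "condition" not in self.samples.columns:
            self.samples["condition"] = (
                "D"
                + self.samples["day"].astype(int).astype(str)
                + "_"
                + self.samples["stiffness"].astype(str)
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.columns)

    def condition_samples(self, condition: str) -> list[str]:
        mask = self.samples["condition"] == condition
        return list(self.samples.index[mask])


@dataclass(frozen=True)
class ComparisonSpec:
    """A pairwise comparison; positive log2fc means higher in condition_B."""

    condition_A: str
    condition_B: str

    def __post_init__(self):
        for c in (self.condition_A, self.condition_B):
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}; expected one of {CONDITIONS}")
        if self.condition_A == self.condition_B:
            raise ValueError("condition_A and condition_B must differ")

    @property
    def name(self) -> str:
        return f"{self.condition_A}_vs_{self.condition_B}"

    def swapped(self) -> "ComparisonSpec":
        return ComparisonSpec(self.condition_B, self.condition_A)


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Rows with a zero in any sample are excluded from the reference; for the
    remaining rows g_i is the geometric mean across samples and
    s_j = median_i(c_ij / g_i).
    """
    mat = counts.table.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has all-positive counts; add a pseudo-reference row "
            "before estimating size factors"
        )
    sub = mat[positive]
    log_gm = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_gm)
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=counts.sample_ids, name="size_factor")


def _group_matrix(counts: CountMatrix, condition: str) -> np.ndarray:
    ids = counts.condition_samples(condition)
    if len(ids) < 2:
        raise ValueError(
            f"condition {condition!r} has {len(ids)} replicate(s); need >= 2"
        )
    return counts.table[ids].to_numpy(dtype=float), ids


def nb_wald_test(
    counts: CountMatrix,
    comparison: ComparisonSpec,
    size_factors: pd.Series,
    prior_df: float = DISPERSION_PRIOR_DF,
) -> pd.DataFrame:
    """Per-feature NB Wald test of condition_B vs condition_A.

    Returns a DataFrame indexed by feature id with columns base_mean, log2fc,
    se, dispersion, wald_z, p, padj, comparison. Features with all-zero
    counts in both groups get log2fc 0 and missing p/padj.
    """
    x_raw, ids_a = _group_matrix(counts, comparison.condition_A)
    y_raw, ids_b = _group_matrix(counts, comparison.condition_B)
    sa = size_factors.loc[ids_a].to_numpy()
    sb = size_factors.loc[ids_b].to_numpy()
    x = x_raw / sa
    y = y_raw / sb
    n_a, n_b = x.shape[1], y.shape[1]
    df_resid = n_a + n_b - 2

    mu_a = x.mean(axis=1)
    mu_b = y.mean(axis=1)
    base_mean = (x.sum(axis=1) + y.sum(axis=1)) / (n_a + n_b)

    ss = ((x - mu_a[:, None]) ** 2).sum(axis=1) + ((y - mu_b[:, None]) ** 2).sum(axis=1)
    pooled_var = ss / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(
            base_mean > 0,
            np.maximum((pooled_var - base_mean) / np.maximum(base_mean, 1e-300) ** 2, DISPERSION_FLOOR),
            np.nan,
        )

    testable = base_mean > 0
    # across-feature trend: mean of the per-feature estimates with the extreme
    # upper tail clipped, so a few outliers cannot inflate everyone's variance
    a_ok = alpha_raw[testable & np.isfinite(alpha_raw)]
    if a_ok.size:
        trend = float(np.mean(np.clip(a_ok, 0.0, np.quantile(a_ok, 0.95))))
        trend = max(trend, DISPERSION_FLOOR)
    else:
        trend = DISPERSION_FLOOR
    alpha = (df_resid * alpha_raw + prior_df * trend) / (df_resid + prior_df)

    c0 = LOG2FC_PSEUDOCOUNT
    log2fc = np.log2((mu_b + c0) / (mu_a + c0))

    var_a = mu_a + alpha * mu_a**2
    var_b = mu_b + alpha * mu_b**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = (
            np.sqrt(var_a / (n_a * (mu_a + c0) ** 2) + var_b / (n_b * (mu_b + c0) ** 2))
            / np.log(2)
        )
    wald_z = np.where(testable & (se > 0), log2fc / np.where(se > 0, se, 1.0), np.nan)
    p = np.where(
        np.isfinite(wald_z), 2 * stats.t.sf(np.abs(wald_z), df_resid + prior_df), np.nan
    )
    log2fc = np.where(testable, log2fc, 0.0)

    padj = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        padj[mask] = bh_adjust(p[mask])

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "dispersion": np.where(testable, alpha, np.nan),
            "wald_z": wald_z,
            "p": p,
            "padj": padj,
            "comparison": comparison.name,
        },
        index=pd.Index(counts.feature_ids, name="feature_id"),
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    results: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
) -> tuple[set, set]:
    """Split a result table into (up, down) feature-id sets.

    up: fold change >= fc_threshold toward condition_B and p below threshold;
    down: symmetric toward condition_A.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be > 0")
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must be in (0, 1]")
    pcol = "padj" if use_adjusted else "p"
    p = results[pcol]
    sig = p.notna() & (p < p_threshold)
    fold = 2.0 ** results["log2fc"]
    up = set(results.index[sig & (fold >= fc_threshold)])
    down = set(results.index[sig & (1.0 / fold >= fc_threshold)])
    return up, down


def write_diff_result(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index_label="feature_id")


def read_diff_result(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")
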