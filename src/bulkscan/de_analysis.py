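"""Negative-binomial differential expression with three-contrast intersection.

The sterile bulk (BY) is contrasted against each normal sample group (KY,
AYP1, XAP1). Counts are normalized by median-of-ratios size factors; each
gene gets a method-of-moments NB dispersion pooled across the two groups of
a contrast, and a two-sided Wald p-value on the normalized mean difference.
Calls use BH-adjusted p < alpha and |log2 fold change| > 1; shared DEGs are
the genes called in the same direction in all three contrasts.

This stage is a from-scratch moments/Wald NB test: simpler than
shrinkage-based estimators, adequate at three replicates, and fully
testable against simulation truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import GROUPS

logger = logging.getLogger(__name__)

#: the three BY-versus-normal contrasts, in reporting order
CONTRASTS = (("BY", "KY"), ("BY", "AYP1"), ("BY", "XAP1"))

_DISPERSION_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5


def group_of(library: str) -> str:
    """Group name of a library id like 'BY_2'."""
    group = library.rsplit("_", 1)[0]
    if group not in GROUPS:
        raise ValueError(f"library {library!r} does not map to a known group")
    return group


def library_groups(counts: pd.DataFrame) -> dict[str, str]:
    return {lib: group_of(lib) for lib in counts.columns}


def validate_counts(counts: pd.DataFrame) -> None:
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")
    groups = library_groups(counts)
    sizes = pd.Series(list(groups.values())).value_counts()
    if (sizes < 2).any():
        raise ValueError("every group needs >= 2 replicates for testing")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    factor_j = median over all-nonzero genes of count_gj / geomean_g. When
    no gene is nonzero in every library, falls back to upper-quartile
    scaling (factors proportional to the 75th percentile of nonzero counts,
    rescaled to geometric mean 1), with a logged notice.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        logmat = np.log(mat[all_nonzero])
        log_geomean = logmat.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logmat - log_geomean, axis=0))
    else:
        logger.warning(
            "no gene with nonzero counts in all libraries; "
            "falling back to upper-quartile size factors"
        )
        uq = np.array(
            [
                np.percentile(col[col > 0], 75) if (col > 0).any() else np.nan
                for col in mat.T
            ]
        )
        if np.isnan(uq).any():
            raise ValueError("a library has no nonzero counts")
        factors = uq / np.exp(np.mean(np.log(uq)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def nb_test_contrast(
    counts: pd.DataFrame,
    group_b: str,
    group_a: str = "BY",
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene (log2fc, p) for one contrast, group_a minus group_b.

    Dispersion is method-of-moments on normalized counts, pooling the
    within-group variances of the two groups, floored at 1e-8; the Wald
    statistic compares normalized group means under NB variance
    mu + alpha mu^2 with a two-sided normal p-value. log2fc uses a 0.5
    pseudocount on each mean. All-zero genes are untestable (p=1, lfc=0).
    """
    validate_counts(counts)
    groups = library_groups(counts)
    libs_a = [l for l in counts.columns if groups[l] == group_a]
    libs_b = [l for l in counts.columns if groups[l] == group_b]
    if not libs_a or not libs_b:
        raise ValueError(f"contrast {group_a} vs {group_b}: missing libraries")
    if factors is None:
        factors = size_factors(counts[libs_a + libs_b])
    norm = counts[libs_a + libs_b].div(factors[libs_a + libs_b], axis=1)
    a = norm[libs_a].to_numpy()
    b = norm[libs_b].to_numpy()
    n_a, n_b = a.shape[1], b.shape[1]
    mu_a = a.mean(axis=1)
    mu_b = b.mean(axis=1)
    mu_pool = np.concatenate([a, b], axis=1).mean(axis=1)

    # pooled within-group method-of-moments dispersion
    var_within = ((a.var(axis=1, ddof=1) * (n_a - 1)) + (b.var(axis=1, ddof=1) * (n_b - 1))) / (
        n_a + n_b - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_within - mu_pool) / np.square(mu_pool)
    alpha = np.where(np.isfinite(alpha), alpha, _DISPERSION_FLOOR)
    alpha = np.maximum(alpha, _DISPERSION_FLOOR)

    var_a = mu_a + alpha * mu_a**2
    var_b = mu_b + alpha * mu_b**2
    se = np.sqrt(var_a / n_a + var_b / n_b)
    untestable = (mu_a == 0) & (mu_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (mu_a - mu_b) / np.where(se > 0, se, 1.0), 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    log2fc = np.log2((mu_a + _PSEUDOCOUNT) / (mu_b + _PSEUDOCOUNT))
    p = np.where(untestable, 1.0, p)
    log2fc = np.where(untestable, 0.0, log2fc)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "mean_a": mu_a,
            "mean_b": mu_b,
            "untestable": untestable,
        },
        index=counts.index,
    )


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


@dataclass
class DEIntersection:
    """Shared-DEG sets plus the per-contrast annotated result tables."""

    shared_up: set[str]
    shared_down: set[str]
    per_contrast: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def counts(self) -> pd.DataFrame:
        rows = [
            {
                "contrast": name,
                "up": int((tab["call"] == "up").sum()),
                "down": int((tab["call"] == "down").sum()),
            }
            for name, tab in self.per_contrast.items()
        ]
        return pd.DataFrame(rows)


def call_and_intersect_degs(
    results: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    lfc: float = 1.0,
    use_adjusted: bool = True,
) -> DEIntersection:
    """BH-adjust each contrast, call up/down/ns, and intersect directions.

    ``shared_up`` are genes called up in *all* supplied contrasts (likewise
    ``shared_down``); a gene can never be in both. With
    ``use_adjusted=False`` the raw p is thresholded instead of the BH
    adjusted one.
    """
    names = list(results)
    universe = None
    for name, tab in results.items():
        genes = set(tab.index)
        if universe is None:
            universe = genes
        elif genes != universe:
            diff = sorted(genes.symmetric_difference(universe))[:10]
            raise ValueError(
                f"contrast {name}: gene set differs from the others, e.g. {diff}"
            )
    annotated: dict[str, pd.DataFrame] = {}
    for name, tab in results.items():
        tab = tab.copy()
        tab["padj"] = bh_adjust(tab["p"])
        crit = tab["padj"] if use_adjusted else tab["p"]
        call = np.where(
            (crit < alpha) & (tab["log2fc"] > lfc),
            "up",
            np.where((crit < alpha) & (tab["log2fc"] < -lfc), "down", "ns"),
        )
        tab["call"] = call
        annotated[name] = tab
    shared_up = set.intersection(
        *(set(t.index[t["call"] == "up"]) for t in annotated.values())
    )
    shared_down = set.intersection(
        *(set(t.index[t["call"] == "down"]) for t in annotated.values())
    )
    return DEIntersection(shared_up, shared_down, annotated)


def run_all_contrasts(
    counts: pd.DataFrame, factors: pd.Series | None = None
) -> dict[str, pd.DataFrame]:
    """The three BY-versus-normal NB tests on one shared normalization."""
    if factors is None:
        factors = size_factors(counts)
    return {
        f"{a}_vs_{b}": nb_test_contrast(counts, group_b=b, group_a=a, factors=factors)
        for a, b in CONTRASTS
    }


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM: count * 1e9 / (gene length in bp * library total count)."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be strictly positive")
    totals = counts.sum(axis=0)
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def group_means(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean of a per-library matrix (counts or FPKM) within each group."""
    groups = library_groups(frame)
    return frame.T.groupby(pd.Series(groups)).mean().T[list(GROUPS)]
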