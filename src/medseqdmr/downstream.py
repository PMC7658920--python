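"""Downstream analyses: Mann-Whitney group tests, supervised clustering,
size-contrast DMRs and probe-level expression validation.

Where the chi-square detector pools reads across samples, these stages go
back to per-sample values: normalized in-DMR read counts per sample for
the rank tests and the heatmap/clustering, probe-level expression values
for the validation stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .counts import SiteCountMatrix
from .dmr import DMR, GroupComparison, sliding_window_dmrs

__all__ = [
    "mannwhitney_u",
    "dmr_sample_matrix",
    "dmr_group_test",
    "ClusteringResult",
    "cluster_samples",
    "size_based_dmrs",
    "ExpressionMatrix",
    "expression_validation",
]

log = logging.getLogger(__name__)


def mannwhitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with U the smaller of the two rank-sum statistics
    (the convention of classical tables).  ``mode``:

    * ``exact`` — exact p by enumeration of labelings;
    * ``normal-approx`` — tie-corrected normal approximation with
      continuity correction;
    * ``auto`` — exact when min(n, m) <= 8 and there are no ties, else
      the normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode == "auto":
        ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
        method = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal-approx":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(min(res.statistic, x.size * y.size - res.statistic))
    return u, float(res.pvalue)


def dmr_sample_matrix(
    dmrs: list[DMR], normalized: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample normalized read counts summed over each DMR's sites.

    Rows are DMRs (labelled ``chrom:start-end``, 1-based inclusive to
    match report tables), columns samples.
    """
    chrom_level = normalized.index.get_level_values("chrom")
    pos_level = normalized.index.get_level_values("pos")
    rows = {}
    for d in dmrs:
        mask = (chrom_level == d.chrom) & (pos_level >= d.start) & (pos_level < d.end)
        rows[f"{d.chrom}:{d.start + 1}-{d.end}"] = normalized.loc[mask].sum(axis=0)
    return pd.DataFrame(rows).T


def dmr_group_test(
    dmrs: list[DMR],
    normalized: pd.DataFrame,
    groups: GroupComparison,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-DMR Mann-Whitney comparison of per-sample normalized counts.

    One row per DMR: group medians, U, two-sided p and a significance
    flag at ``alpha``.
    """
    mat = dmr_sample_matrix(dmrs, normalized)
    rows = []
    for (label, values), d in zip(mat.iterrows(), dmrs):
        xa = values[groups.a_samples].to_numpy()
        xb = values[groups.b_samples].to_numpy()
        u, p = mannwhitney_u(xa, xb)
        rows.append(
            {
                "dmr": label,
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                f"median_{groups.label_a}": float(np.median(xa)),
                f"median_{groups.label_b}": float(np.median(xb)),
                "U": u,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ClusteringResult:
    """Hierarchical clustering of samples on DMR methylation."""

    order: list[str]
    linkage_matrix: np.ndarray
    assignments: pd.Series  # 2-cut cluster label per sample
    purity: pd.DataFrame
    matrix: pd.DataFrame  # transformed DMR x sample values, row order as input
    samples: list[str] = field(default_factory=list)

    def to_newick(self) -> str:
        """The merge tree in newick format with branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.samples[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def _two_cut_purity(assignments: pd.Series, covariate: pd.Series) -> float:
    """How cleanly a 2-cut separates a covariate's levels.

    For each cluster take its majority level; purity is the fraction of
    samples matching their cluster's majority (1.0 = perfect separation,
    ~0.5 = none for a balanced binary covariate).
    """
    total = 0
    n = 0
    for _, members in covariate.groupby(assignments):
        total += int(members.value_counts().iloc[0])
        n += len(members)
    return total / n if n else float("nan")


def cluster_samples(
    matrix: pd.DataFrame,
    sample_sheet: "pd.DataFrame | None" = None,
    linkage: str = "average",
    metric: str = "euclidean",
    size_thresholds: tuple[float, float] = (34.0, 87.0),
    transform: bool = True,
) -> ClusteringResult:
    """Hierarchically cluster samples on DMR methylation values.

    ``matrix`` is DMR x sample normalized read counts (selection of the
    DMRs is the supervised step; the clustering itself is unsupervised).
    Rows are log2(x+1)-transformed and z-scored per DMR when ``transform``
    (constant rows become zeros), then samples are clustered on column
    vectors with the given linkage and metric.  The leaf order is
    deterministic: scipy's ordering with sample-sheet (input column)
    order breaking ties by construction.

    The purity summary reports, for each covariate present in the sample
    sheet (group, sex, tumor_site and a size class cut at the given
    thresholds), how cleanly cutting the tree into two clusters separates
    the covariate's levels.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    X = matrix.to_numpy(dtype=float)
    if transform:
        X = np.log2(X + 1.0)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    dist = pdist(X.T, metric=metric)
    Z = hierarchy.linkage(dist, method=linkage)
    samples = list(matrix.columns)
    order = [samples[i] for i in hierarchy.leaves_list(Z)]
    assignments = pd.Series(
        hierarchy.fcluster(Z, t=2, criterion="maxclust"), index=samples, name="cluster"
    )

    purity_rows = []
    if sample_sheet is not None:
        sheet = sample_sheet.set_index("sample_id").loc[samples]
        covariates: dict[str, pd.Series] = {}
        for col in ("group", "sex", "tumor_site"):
            if col in sheet.columns:
                covariates[col] = sheet[col]
        if "size_mm" in sheet.columns:
            small, large = size_thresholds
            size_class = pd.Series(
                np.where(
                    sheet["size_mm"].isna(),
                    "unknown",
                    np.where(sheet["size_mm"] <= small, "small",
                             np.where(sheet["size_mm"] > large, "large", "mid")),
                ),
                index=sheet.index,
            )
            covariates["size_class"] = size_class
        for name, cov in covariates.items():
            purity_rows.append(
                {"covariate": name, "purity": _two_cut_purity(assignments, cov)}
            )
    purity = pd.DataFrame(purity_rows, columns=["covariate", "purity"])
    transformed = pd.DataFrame(X, index=matrix.index, columns=samples)
    return ClusteringResult(
        order=order,
        linkage_matrix=Z,
        assignments=assignments,
        purity=purity,
        matrix=transformed,
        samples=samples,
    )


def size_based_dmrs(
    matrix: SiteCountMatrix,
    sample_sheet: pd.DataFrame,
    small_max: float = 34.0,
    large_min: float = 87.0,
    **detect_kwargs,
) -> tuple[list[DMR], GroupComparison]:
    """DMRs between size-extreme tumors (small <= ``small_max`` mm,
    large > ``large_min`` mm).

    Samples with missing size are excluded (logged).  Delegates detection
    to the sliding-window chi-square caller with the size classes as the
    two groups; raises when either class is empty.
    """
    sized = sample_sheet.dropna(subset=["size_mm"])
    dropped = len(sample_sheet) - len(sized)
    if dropped:
        log.info("excluding %d samples with missing size", dropped)
    small = sized.loc[sized["size_mm"] <= small_max, "sample_id"].tolist()
    large = sized.loc[sized["size_mm"] > large_min, "sample_id"].tolist()
    if not small or not large:
        raise ValueError(
            f"empty size class for thresholds <= {small_max} mm / > {large_min} mm "
            f"(small n={len(small)}, large n={len(large)})"
        )
    groups = GroupComparison(small, large, label_a="small", label_b="large")
    return sliding_window_dmrs(matrix, groups, **detect_kwargs), groups


@dataclass
class ExpressionMatrix:
    """Probe x sample expression values with a probe -> gene mapping."""

    values: pd.DataFrame
    probe_to_gene: pd.Series

    def __post_init__(self) -> None:
        unknown = set(self.values.index) - set(self.probe_to_gene.index)
        if unknown:
            raise ValueError(f"probes without gene mapping: {sorted(unknown)[:5]}")

    def probes_for(self, gene: str) -> list[str]:
        return [p for p, g in self.probe_to_gene.items() if g == gene and p in self.values.index]


def expression_validation(
    expr: ExpressionMatrix,
    groups: GroupComparison,
    genes: list[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Probe-level Mann-Whitney validation of DMR-associated genes.

    One output row per probe of each requested gene: pooled median and
    IQR over all samples of both groups, U and two-sided p between the
    groups.  Genes with no probe on the platform are returned in the
    skipped list rather than raising.
    """
    rows = []
    skipped = []
    samples = groups.a_samples + groups.b_samples
    for gene in genes:
        probes = expr.probes_for(gene)
        if not probes:
            skipped.append(gene)
            continue
        for probe in probes:
            values = expr.values.loc[probe, samples]
            xa = expr.values.loc[probe, groups.a_samples].to_numpy()
            xb = expr.values.loc[probe, groups.b_samples].to_numpy()
            u, p = mannwhitney_u(xa, xb)
            q1, q3 = np.percentile(values, [25, 75])
            rows.append(
                {
                    "gene": gene,
                    "probe": probe,
                    "median": float(np.median(values)),
                    "iqr_low": float(q1),
                    "iqr_high": float(q3),
                    "U": u,
                    "p": p,
                    "significant": p < alpha,
                }
            )
    if skipped:
        log.warning("genes with no probe on the platform: %s", skipped)
    return pd.DataFrame(
        rows,
        columns=["gene", "probe", "median", "iqr_low", "iqr_high", "U", "p", "significant"],
    ), skipped
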