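"""Chi-square DMR detection, multiple-testing correction and annotation.

The test of record is a pooled Pearson chi-square on read counts: for a
site or region, counts are summed over the samples of each group and laid
out against the remainder of that group's library,

    =========  ==============  ==========================
    group      in feature      rest of library
    =========  ==============  ==========================
    A          a               b = library_A - a
    B          c               d = library_B - c
    =========  ==============  ==========================

which makes library-size normalization implicit.  Two detection modes are
provided: region mode (test each annotated TSS / gene-body / CpG-island
region) and a genome-wide sliding window (test each LpnPI site, bin
neighboring significant sites into candidate DMRs, re-test each DMR on its
pooled counts).  Candidates are corrected by Benjamini-Hochberg (default)
or Bonferroni, oriented by fold change of group-mean normalized counts,
and filtered on fold change and sex chromosomes.

There is no per-sample replication model: the chi-square treats each
group's pooled library as one multinomial draw.  With biological
overdispersion across samples the test is therefore anti-conservative;
the calibration guarantees in the test-suite hold under Poisson counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import SiteCountMatrix
from .regions import RegionCountMatrix, RegionDefinition

__all__ = [
    "DegenerateTableError",
    "GroupComparison",
    "DMR",
    "chisq_2x2",
    "adjust_pvalues",
    "test_regions",
    "sliding_window_dmrs",
    "bin_significant_sites",
    "compute_fold_change",
    "filter_dmrs",
    "annotate_dmrs",
]

log = logging.getLogger(__name__)

SEX_CHROMOSOMES = ("X", "Y", "chrX", "chrY")


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero row or column margin; no test is defined."""


@dataclass
class GroupComparison:
    """The two pooled sample groups a comparison runs between."""

    a_samples: list[str]
    b_samples: list[str]
    label_a: str = "S45F"
    label_b: str = "T41A"

    def __post_init__(self) -> None:
        if not self.a_samples or not self.b_samples:
            raise ValueError("both groups must be non-empty")
        overlap = set(self.a_samples) & set(self.b_samples)
        if overlap:
            raise ValueError(f"groups overlap: {sorted(overlap)}")

    @classmethod
    def from_sample_sheet(
        cls, sheet: pd.DataFrame, column: str = "group",
        label_a: str = "S45F", label_b: str = "T41A",
    ) -> "GroupComparison":
        a = sheet.loc[sheet[column] == label_a, "sample_id"].tolist()
        b = sheet.loc[sheet[column] == label_b, "sample_id"].tolist()
        return cls(a, b, label_a, label_b)

    def swapped(self) -> "GroupComparison":
        return GroupComparison(self.b_samples, self.a_samples, self.label_b, self.label_a)


@dataclass
class DMR:
    """One called differentially methylated region.

    Coordinates are internal 0-based half-open; report writers convert to
    1-based inclusive.  ``status`` maps each group label to "+"
    (hypermethylated), "−" (hypomethylated) or "=" (tied).
    """

    chrom: str
    start: int
    end: int
    n_sites: int
    chi2: float
    p: float
    q: float
    method: str
    fold_change: float = float("nan")
    status: dict = field(default_factory=dict)
    genes: list = field(default_factory=list)
    position_label: str = "none"
    cpg_island: bool = False
    region_id: str = ""


def chisq_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Raises :class:`DegenerateTableError` when a row or column margin is
    zero; callers treat such features as untestable (p = 1) and skip them.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise DegenerateTableError(f"zero margin in table ({a}, {b}, {c}, {d})")
    stat, p = _chi2_vec(
        np.array([a], float), np.array([b], float),
        np.array([c], float), np.array([d], float),
    )
    return float(stat[0]), float(p[0])


def _chi2_vec(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson chi-square; degenerate tables get stat 0, p 1."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    ok = denom > 0
    stat = np.zeros_like(a, dtype=float)
    det = a * d - b * c
    stat[ok] = n[ok] * det[ok] ** 2 / denom[ok]
    p = np.ones_like(stat)
    p[ok] = stats.chi2.sf(stat[ok], df=1)
    return stat, p


def adjust_pvalues(
    p_values, method: str = "bh", family_size: "int | None" = None
) -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni or Benjamini-Hochberg.

    ``family_size`` widens the correction family beyond the p-values
    supplied — used when candidates were pre-selected from a larger scan
    (the sliding window tests every site but re-tests only binned runs).
    Adjusted values are monotone in rank and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(family_size) if family_size is not None else p.size
    if m < p.size:
        raise ValueError("family_size cannot be smaller than the number of p-values")
    method = method.lower()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method in ("bh", "fdr_bh"):
        if m == p.size:
            return multipletests(p, method="fdr_bh")[1]
        # step-up with an enlarged family: q_(i) = min_{j>=i} p_(j) * m / j
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, p.size + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(q)
        out[order] = np.minimum(q, 1.0)
        return out
    raise ValueError(f"unknown correction method {method!r}")


def _group_totals(
    counts: pd.DataFrame, library_sizes: pd.Series, groups: GroupComparison
) -> tuple[np.ndarray, np.ndarray, float, float]:
    a = counts[groups.a_samples].sum(axis=1).to_numpy(dtype=float)
    b = counts[groups.b_samples].sum(axis=1).to_numpy(dtype=float)
    lib_a = float(library_sizes[groups.a_samples].sum())
    lib_b = float(library_sizes[groups.b_samples].sum())
    return a, b, lib_a, lib_b


def test_regions(
    region_matrix: RegionCountMatrix,
    groups: GroupComparison,
    site_matrix: "SiteCountMatrix | None" = None,
    alpha: float = 0.05,
    method: str = "bh",
    pseudocount: float = 0.5,
) -> list[DMR]:
    """Region-mode DMR detection.

    Each region's pooled group counts are tested against the remainder of
    each group's library; regions whose adjusted p falls below ``alpha``
    are returned as DMRs, oriented by fold change of group-mean normalized
    region counts.  Degenerate tables (zero margins) are skipped with a
    log message.  ``site_matrix`` is only used to compute fold changes on
    site-level normalized counts; when omitted, region-level normalized
    counts are used directly.
    """
    counts = region_matrix.counts
    a, b, lib_a, lib_b = _group_totals(counts, region_matrix.library_sizes, groups)
    stat, p = _chi2_vec(a, lib_a - a, b, lib_b - b)
    degenerate = ((a + (lib_a - a)) == 0) | ((b + (lib_b - b)) == 0) | ((a + b) == 0)
    if degenerate.any():
        log.info("skipping %d degenerate regions", int(degenerate.sum()))
    q = adjust_pvalues(p, method=method)
    norm = region_matrix.normalized()
    out: list[DMR] = []
    for i, r in enumerate(region_matrix.regions):
        if degenerate[i] or q[i] >= alpha:
            continue
        fc, status = _fold_change_from_values(
            norm.iloc[i][groups.a_samples].mean(),
            norm.iloc[i][groups.b_samples].mean(),
            groups,
            pseudocount,
        )
        if site_matrix is not None:
            fc, status = compute_fold_change(
                (r.chrom, r.start, r.end), site_matrix.normalized(), groups, pseudocount
            )
        out.append(
            DMR(
                chrom=r.chrom,
                start=r.start,
                end=r.end,
                n_sites=int(region_matrix.n_sites.iloc[i]),
                chi2=float(stat[i]),
                p=float(p[i]),
                q=float(q[i]),
                method=method,
                fold_change=fc,
                status=status,
                genes=[r.gene_id] if r.gene_id else [],
                position_label={"TSS": "TSS", "gene_body": "postTSS1KB-TES"}.get(
                    r.region_class, "none"
                ),
                cpg_island=r.region_class == "cpg_island",
                region_id=r.region_id,
            )
        )
    out.sort(key=lambda d: d.q)
    return out


def bin_significant_sites(
    positions: np.ndarray,
    significant: np.ndarray,
    max_gap: int,
    min_sites: int,
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive significant sites on one chromosome.

    A run extends while the next site is significant and within
    ``max_gap`` bases of the previous one; runs with fewer than
    ``min_sites`` sites are dropped.  Returns (first, last) index pairs
    into ``positions`` (inclusive).
    """
    runs: list[tuple[int, int]] = []
    start = None
    for i in range(len(positions)):
        if significant[i]:
            if start is None:
                start = i
            elif positions[i] - positions[i - 1] > max_gap:
                if i - start >= min_sites:
                    runs.append((start, i - 1))
                start = i
        else:
            if start is not None and i - start >= min_sites:
                runs.append((start, i - 1))
            start = None
    if start is not None and len(positions) - start >= min_sites:
        runs.append((start, len(positions) - 1))
    return runs


def sliding_window_dmrs(
    matrix: SiteCountMatrix,
    groups: GroupComparison,
    site_alpha: float = 0.05,
    min_sites: int = 2,
    max_gap: int = 1000,
    alpha: float = 0.05,
    method: str = "bh",
    correction_family: str = "sites",
    pseudocount: float = 0.5,
) -> list[DMR]:
    """Genome-wide sliding-window DMR detection.

    Every LpnPI site is chi-square tested (pooled group count vs library
    remainder); sites with raw p < ``site_alpha`` seed candidate DMRs by
    binning neighboring significant sites (inter-site distance at most
    ``max_gap``, at least ``min_sites`` sites).  Each candidate is then
    re-tested on its pooled counts and the candidate p-values are
    corrected with ``method``.  Because candidates emerge from a
    genome-wide scan, the default correction family is the number of
    sites tested (``correction_family="sites"``), which keeps the null
    false-call rate at the nominal level; ``"candidates"`` corrects over
    the binned runs only.  DMRs with adjusted p < ``alpha`` are returned,
    spanning first to last site of the run (half-open end = last site + 1).
    """
    counts = matrix.counts
    a, b, lib_a, lib_b = _group_totals(counts, matrix.library_sizes, groups)
    _, p_site = _chi2_vec(a, lib_a - a, b, lib_b - b)
    sig = p_site < site_alpha

    chrom_level = counts.index.get_level_values("chrom").to_numpy()
    pos_level = counts.index.get_level_values("pos").to_numpy()
    norm = matrix.normalized()

    candidates: list[tuple[str, int, int]] = []  # chrom, first idx, last idx
    if len(chrom_level):
        change = np.flatnonzero(chrom_level[1:] != chrom_level[:-1])
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [len(chrom_level)]])
        for s, e in zip(starts, ends):
            for i0, i1 in bin_significant_sites(
                pos_level[s:e], sig[s:e], max_gap, min_sites
            ):
                candidates.append((str(chrom_level[s]), int(s + i0), int(s + i1)))

    if not candidates:
        return []
    pooled_stat = np.empty(len(candidates))
    pooled_p = np.empty(len(candidates))
    for k, (_, i0, i1) in enumerate(candidates):
        pa, pb = a[i0 : i1 + 1].sum(), b[i0 : i1 + 1].sum()
        s, p = _chi2_vec(
            np.array([pa]), np.array([lib_a - pa]),
            np.array([pb]), np.array([lib_b - pb]),
        )
        pooled_stat[k], pooled_p[k] = s[0], p[0]
    family = matrix.n_sites if correction_family == "sites" else None
    q = adjust_pvalues(pooled_p, method=method, family_size=family)

    out: list[DMR] = []
    for k, (chrom, i0, i1) in enumerate(candidates):
        if q[k] >= alpha:
            continue
        start, end = int(pos_level[i0]), int(pos_level[i1]) + 1
        fc, status = compute_fold_change((chrom, start, end), norm, groups, pseudocount)
        out.append(
            DMR(
                chrom=chrom,
                start=start,
                end=end,
                n_sites=i1 - i0 + 1,
                chi2=float(pooled_stat[k]),
                p=float(pooled_p[k]),
                q=float(q[k]),
                method=method,
                fold_change=fc,
                status=status,
            )
        )
    out.sort(key=lambda d: (d.chrom, d.start))
    return out


def _fold_change_from_values(
    mean_a: float, mean_b: float, groups: GroupComparison, pseudocount: float
) -> tuple[float, dict]:
    ma, mb = mean_a + pseudocount, mean_b + pseudocount
    if ma == mb:
        return 1.0, {groups.label_a: "=", groups.label_b: "="}
    if ma > mb:
        return ma / mb, {groups.label_a: "+", groups.label_b: "-"}
    return mb / ma, {groups.label_a: "-", groups.label_b: "+"}


def compute_fold_change(
    interval: tuple[str, int, int],
    normalized: pd.DataFrame,
    groups: GroupComparison,
    pseudocount: float = 0.5,
) -> tuple[float, dict]:
    """Fold change and methylation status of a DMR interval.

    Normalized counts of the sites inside ``[start, end)`` are summed per
    sample and averaged per group; the fold change is the larger group
    mean over the smaller (pseudocount added to both means, in normalized
    units), so it is always >= 1.  The group with the larger mean is "+"
    (hypermethylated), the other "−"; exactly equal means give fold
    change 1 and both statuses "=".
    """
    chrom, start, end = interval
    chrom_level = normalized.index.get_level_values("chrom")
    pos_level = normalized.index.get_level_values("pos")
    mask = (chrom_level == chrom) & (pos_level >= start) & (pos_level < end)
    sub = normalized.loc[mask]
    per_sample = sub.sum(axis=0)
    return _fold_change_from_values(
        float(per_sample[groups.a_samples].mean()),
        float(per_sample[groups.b_samples].mean()),
        groups,
        pseudocount,
    )


def canonical_chrom(name: str) -> str:
    """Strip a ``chr`` prefix: ``chrX`` -> ``X``; alt contigs unchanged."""
    return name[3:] if name.startswith("chr") else name


def filter_dmrs(
    dmrs: list[DMR],
    fc_threshold: float = 1.5,
    exclude_sex: bool = True,
    sex_names: tuple = SEX_CHROMOSOMES,
) -> list[DMR]:
    """Keep DMRs with fold change >= ``fc_threshold``, dropping sex
    chromosomes when ``exclude_sex``.

    Sex-chromosome matching is on the exact canonical name only (``X``,
    ``Y``, ``chrX``, ``chrY``); alt contigs whose name merely embeds a
    chromosome string are retained.
    """
    out = []
    for d in dmrs:
        if exclude_sex and d.chrom in sex_names:
            continue
        if not (d.fold_change >= fc_threshold):  # NaN fails closed
            continue
        out.append(d)
    return out


def annotate_dmrs(
    dmrs: list[DMR], regions: list[RegionDefinition]
) -> list[DMR]:
    """Annotate DMRs with overlapping genes and a position label.

    A DMR overlapping any gene's TSS window is labelled ``TSS``;
    overlapping only gene bodies, ``postTSS1KB-TES``; no gene overlap
    leaves the gene list empty and the label ``none``.  CpG-island
    overlap is recorded as a separate flag.  Overlap is any shared base
    between half-open intervals.  The input list is annotated in place
    and returned.
    """
    by_chrom: dict[str, list[RegionDefinition]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for d in dmrs:
        genes: list[str] = []
        has_tss = has_body = has_island = False
        for r in by_chrom.get(d.chrom, []):
            if r.start < d.end and d.start < r.end:
                if r.region_class == "cpg_island":
                    has_island = True
                    continue
                if r.gene_id and r.gene_id not in genes:
                    genes.append(r.gene_id)
                if r.region_class == "TSS":
                    has_tss = True
                elif r.region_class == "gene_body":
                    has_body = True
        d.genes = sorted(genes)
        d.cpg_island = has_island
        d.position_label = "TSS" if has_tss else ("postTSS1KB-TES" if has_body else "none")
    return dmrs
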