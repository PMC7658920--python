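"""Annotated region classes and region-level read-count scoring.

Site counts are aggregated into the three region classes the comparison
is scored on:

* ``TSS`` — 1 kb before to 1 kb after the transcription start site
  (2,000 bases exactly, strand-aware);
* ``gene_body`` — from 1 kb after the TSS to the transcription end site
  (label ``postTSS1KB-TES`` in report tables);
* ``cpg_island`` — CpG-island intervals from the annotation.

Overlapping regions each receive a contained site's counts; there is no
exclusive assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import SiteCountMatrix, normalize_counts
from .genome import GeneAnnotation

__all__ = [
    "TSS_FLANK",
    "RegionDefinition",
    "RegionCountMatrix",
    "build_regions",
    "score_regions",
]

log = logging.getLogger(__name__)

#: Bases on each side of the TSS forming the TSS window; also the distance
#: past the TSS at which the gene body starts.
TSS_FLANK = 1000

REGION_CLASSES = ("TSS", "gene_body", "cpg_island")


@dataclass
class RegionDefinition:
    """One scored interval; 0-based half-open."""

    region_id: str
    region_class: str
    chrom: str
    start: int
    end: int
    gene_id: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if not self.start < self.end:
            raise ValueError(
                f"region {self.region_id}: start ({self.start}) must be < end ({self.end})"
            )


@dataclass
class RegionCountMatrix:
    """Region x sample summed counts plus the site-level library sizes.

    ``counts`` rows follow ``regions`` order; ``n_sites`` records how many
    LpnPI sites each region contains; ``library_sizes`` are carried from
    the site matrix so normalization applies the same per-sample factor.
    """

    counts: pd.DataFrame
    regions: list[RegionDefinition]
    n_sites: pd.Series
    library_sizes: pd.Series

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def normalized(self) -> pd.DataFrame:
        return normalize_counts(self.counts, self.library_sizes)

    def region(self, region_id: str) -> RegionDefinition:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)


def build_regions(
    genes: list[GeneAnnotation],
    islands: "list[tuple[str, int, int]] | None" = None,
    chrom_lengths: "dict[str, int] | None" = None,
    tss_flank: int = TSS_FLANK,
) -> list[RegionDefinition]:
    """Region definitions for every gene and CpG island.

    For a + strand gene with TSS ``t``: TSS window ``[t - 1000, t + 1000)``
    and gene body ``[t + 1000, TES)``.  For a − strand gene the windows
    mirror strand-aware (TSS at the gene end, body running back to the
    start).  Regions are clipped to chromosome bounds when lengths are
    given.  Genes shorter than 2 kb yield a TSS window only (logged).
    """
    out: list[RegionDefinition] = []
    for g in genes:
        t = g.tss
        tss_start, tss_end = t - tss_flank, t + tss_flank
        if g.strand == "+":
            body = (t + tss_flank, g.end)
        else:
            body = (g.start, t - tss_flank)
        if chrom_lengths is not None:
            ln = chrom_lengths[g.chrom]
            tss_start, tss_end = max(0, tss_start), min(ln, tss_end)
        if tss_start < tss_end:
            out.append(
                RegionDefinition(
                    f"{g.gene_id}:TSS", "TSS", g.chrom, tss_start, tss_end, g.gene_id, g.strand
                )
            )
        if g.length >= 2 * tss_flank and body[0] < body[1]:
            out.append(
                RegionDefinition(
                    f"{g.gene_id}:body",
                    "gene_body",
                    g.chrom,
                    body[0],
                    body[1],
                    g.gene_id,
                    g.strand,
                )
            )
        else:
            log.warning(
                "gene %s is shorter than %d bases; gene body region omitted",
                g.gene_id,
                2 * tss_flank,
            )
    for i, (chrom, start, end) in enumerate(islands or []):
        out.append(RegionDefinition(f"CGI_{i:04d}", "cpg_island", chrom, start, end))
    return out


def score_regions(
    matrix: SiteCountMatrix, regions: list[RegionDefinition]
) -> RegionCountMatrix:
    """Sum site counts into each region's half-open interval.

    A site lying in two overlapping regions contributes to both; a site
    exactly at ``end`` is excluded (half-open), so a gene's TSS window and
    body partition ``[t - 1000, TES)`` without double counting.
    """
    chrom_level = matrix.counts.index.get_level_values("chrom").to_numpy()
    pos_level = matrix.counts.index.get_level_values("pos").to_numpy()
    values = matrix.counts.to_numpy()
    # positional slices per chromosome (site index is chromosome-blocked)
    blocks: dict[str, tuple[int, int]] = {}
    if len(chrom_level):
        change = np.flatnonzero(chrom_level[1:] != chrom_level[:-1])
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [len(chrom_level)]])
        blocks = {str(chrom_level[s]): (int(s), int(e)) for s, e in zip(starts, ends)}

    rows = np.zeros((len(regions), values.shape[1]), dtype=int)
    n_sites = np.zeros(len(regions), dtype=int)
    for i, r in enumerate(regions):
        blk = blocks.get(r.chrom)
        if blk is None:
            continue
        s, e = blk
        pos = pos_level[s:e]
        lo = s + np.searchsorted(pos, r.start, side="left")
        hi = s + np.searchsorted(pos, r.end, side="left")
        n_sites[i] = hi - lo
        if hi > lo:
            rows[i] = values[lo:hi].sum(axis=0)
    ids = [r.region_id for r in regions]
    counts = pd.DataFrame(rows, index=ids, columns=matrix.counts.columns)
    return RegionCountMatrix(
        counts=counts,
        regions=list(regions),
        n_sites=pd.Series(n_sites, index=ids),
        library_sizes=matrix.library_sizes,
    )
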