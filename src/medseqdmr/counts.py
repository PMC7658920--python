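"""The pipeline's central container: LpnPI sites x samples read counts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SiteCountMatrix", "site_index", "normalize_counts"]


def site_index(sites: pd.DataFrame) -> pd.MultiIndex:
    """(chrom, pos) MultiIndex from a site table, preserving row order."""
    return pd.MultiIndex.from_arrays(
        [sites["chrom"].to_numpy(), sites["pos"].to_numpy()], names=["chrom", "pos"]
    )


@dataclass
class SiteCountMatrix:
    """Integer read counts per (LpnPI site, sample).

    ``counts`` is indexed by a (chrom, pos) MultiIndex sorted by chromosome
    then position; columns are sample ids.  The per-sample library size is
    the column sum — the total of filter-passing reads assigned to any site.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.index.names) != ["chrom", "pos"]:
            raise ValueError("counts must be indexed by (chrom, pos)")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        pos = self.counts.index.get_level_values("pos").to_numpy()
        chrom = self.counts.index.get_level_values("chrom").to_numpy()
        breaks = np.flatnonzero(chrom[1:] != chrom[:-1])
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for s, e in zip(starts, ends):
            if np.any(np.diff(pos[s:e]) < 0):
                raise ValueError(f"site positions unsorted within {chrom[s]}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n_sites(self) -> int:
        return len(self.counts)

    def normalized(self) -> pd.DataFrame:
        """Counts-per-million per sample (columns sum to 1e6)."""
        return normalize_counts(self.counts, self.library_sizes)

    def sites(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.counts.index.get_level_values("chrom"),
                "pos": self.counts.index.get_level_values("pos"),
            }
        ).reset_index(drop=True)


def normalize_counts(
    counts: pd.DataFrame, library_sizes: "pd.Series | None" = None
) -> pd.DataFrame:
    """Scale each sample column to counts per million of its library size.

    For the site-level matrix the library size is the column sum, so every
    normalized column sums to exactly 1e6.  Region-level matrices pass the
    site-level library sizes so regions are scaled by the same per-sample
    factor.  Raises ``ValueError`` naming any sample with a zero library.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    zero = library_sizes[library_sizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts * (1e6 / library_sizes)
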