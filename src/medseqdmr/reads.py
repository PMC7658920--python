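"""MeD-seq read filtering and conversion to the site count matrix.

A genuine LpnPI digestion product carries the recognition CpG at a fixed
distance from the cut, so real fragments place the site's C 13-17 bp from
one read end.  The filter keeps a read iff at least one candidate LpnPI
site lies at an offset in the closed window [13, 17] from the 5' end OR
from the 3' end; everything else is discarded as off-target.  Kept reads
are then attributed to exactly one site each, yielding the genome-wide
site x sample count matrix.

Alignment is out of scope: synthetic mode uses the simulator's truth
placement, real-data mode ingests pre-mapped positions (a BED-like table)
and recomputes candidate offsets against the site index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import SiteCountMatrix, site_index

__all__ = [
    "FILTER_WINDOW",
    "FilterReport",
    "offset_passes",
    "candidate_offsets",
    "filter_reads",
    "assign_reads_to_sites",
]

#: Closed window of accepted site offsets from either read end, in bases.
FILTER_WINDOW = (13, 17)


@dataclass
class FilterReport:
    """Bookkeeping for one filter pass; kept + discarded = input."""

    n_input: int = 0
    n_kept: int = 0
    n_discarded: int = 0
    n_no_candidate: int = 0
    n_out_of_window: int = 0
    kept_per_sample: dict = field(default_factory=dict)

    def check(self) -> None:
        assert self.n_kept + self.n_discarded == self.n_input


def offset_passes(
    offset: int, read_length: int, window: tuple[int, int] = FILTER_WINDOW
) -> bool:
    """True iff a site at 5'-offset ``offset`` passes the end-distance filter.

    The 3' distance of a base at 0-based 5'-offset ``o`` in a read of
    length ``L`` is ``L - 1 - o``; both distances are tested against the
    closed window.
    """
    lo, hi = window
    three = read_length - 1 - offset
    return lo <= offset <= hi or lo <= three <= hi


def candidate_offsets(reads: pd.DataFrame, sites: pd.DataFrame) -> list[np.ndarray]:
    """5'-offsets of every LpnPI site falling inside each mapped read.

    ``reads`` needs columns chrom, start, length; ``sites`` columns chrom,
    pos.  Reads on chromosomes absent from the site index get an empty
    candidate list.  Offsets are relative to the mapped start regardless of
    strand (single-end reads are reported on the forward strand).
    """
    by_chrom: dict[str, np.ndarray] = {
        str(c): np.sort(g["pos"].to_numpy())
        for c, g in sites.groupby("chrom", sort=False)
    }
    out: list[np.ndarray] = []
    for row in reads.itertuples(index=False):
        pos = by_chrom.get(str(row.chrom))
        if pos is None:
            out.append(np.empty(0, dtype=int))
            continue
        lo = np.searchsorted(pos, row.start, side="left")
        hi = np.searchsorted(pos, row.start + row.length, side="left")
        out.append(pos[lo:hi] - int(row.start))
    return out


def filter_reads(
    reads: pd.DataFrame,
    offsets: "list[np.ndarray] | None" = None,
    sites: "pd.DataFrame | None" = None,
    window: tuple[int, int] = FILTER_WINDOW,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the LpnPI end-distance filter to mapped reads.

    ``reads`` is a table with columns read_id, chrom, start, length (plus
    any carry-through columns such as sample).  Candidate site offsets are
    either supplied per read (``offsets``, 5'-offsets in bases) or computed
    from a site index (``sites``).  Returns the kept rows — with the
    offset of the accepted site in a ``site_offset`` column and its genomic
    position in ``site_pos`` — and a :class:`FilterReport`.

    When a read has several in-window candidates the one with the smallest
    genomic position (= smallest offset) is attributed.
    """
    if offsets is None:
        if sites is None:
            raise ValueError("provide per-read offsets or a site table")
        offsets = candidate_offsets(reads, sites)
    if len(offsets) != len(reads):
        raise ValueError(
            f"offsets ({len(offsets)}) do not match reads ({len(reads)})"
        )
    report = FilterReport(n_input=len(reads))
    keep_rows = []
    lengths = reads["length"].to_numpy()
    starts = reads["start"].to_numpy()
    for i, cand in enumerate(offsets):
        cand = np.asarray(cand, dtype=int)
        if cand.size == 0:
            report.n_no_candidate += 1
            report.n_discarded += 1
            continue
        passing = cand[
            [offset_passes(int(o), int(lengths[i]), window) for o in cand]
        ]
        if passing.size == 0:
            report.n_out_of_window += 1
            report.n_discarded += 1
            continue
        off = int(passing.min())  # tie-break: smallest genomic position
        keep_rows.append((i, off, int(starts[i]) + off))
        report.n_kept += 1
    if keep_rows:
        idx, offs, poss = zip(*keep_rows)
        kept = reads.iloc[list(idx)].copy()
        kept["site_offset"] = offs
        kept["site_pos"] = poss
    else:
        kept = reads.iloc[:0].copy()
        kept["site_offset"] = pd.Series(dtype=int)
        kept["site_pos"] = pd.Series(dtype=int)
    if "sample" in kept.columns:
        report.kept_per_sample = kept["sample"].value_counts().to_dict()
    report.check()
    return kept.reset_index(drop=True), report


def assign_reads_to_sites(
    kept: pd.DataFrame,
    sites: pd.DataFrame,
    samples: "list[str] | None" = None,
) -> tuple[SiteCountMatrix, int]:
    """Tally filter-passing reads into the site x sample count matrix.

    Each kept read increments exactly one site — the (chrom, site_pos)
    recorded by the filter.  Reads whose attributed position is absent
    from the site index (e.g. a chromosome not in the index) are dropped
    and returned as the unassigned count.  ``samples`` fixes the column
    set and order; by default the samples present in ``kept`` are used.
    """
    sites = sites.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    idx = site_index(sites)
    if samples is None:
        samples = sorted(kept["sample"].unique()) if len(kept) else []
    mat = pd.DataFrame(0, index=idx, columns=list(samples), dtype=int)
    unassigned = 0
    if len(kept):
        key = pd.MultiIndex.from_arrays(
            [kept["chrom"].to_numpy(), kept["site_pos"].to_numpy()],
            names=["chrom", "pos"],
        )
        known = key.isin(idx)
        unassigned = int((~known).sum())
        tally = (
            pd.DataFrame({"sample": kept["sample"].to_numpy()[known]}, index=key[known])
            .groupby(["chrom", "pos", "sample"])
            .size()
        )
        for (chrom, pos, sample), n in tally.items():
            mat.loc[(chrom, pos), sample] = int(n)
    return SiteCountMatrix(mat), unassigned
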