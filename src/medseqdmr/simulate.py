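"""Synthetic MeD-seq data: methylation profiles, digestion, reads, counts.

This module is the ground-truth generator the pipeline is validated
against.  It emulates the physics of the assay at desk scale:

* a latent methylation fraction per LpnPI site per sample, with
  group-differential regions injected at configurable fold change;
* LpnPI digestion, which excises a 32-bp fragment around each methylated
  CpG by cutting 16 bp downstream of the site;
* 50-nt single-end reads taken from those fragments, with a truth table
  recording which site produced each read and at what offset;
* or, bypassing the read level, negative-binomial per-site counts whose
  expectation is depth x methylation.

Every operation takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import cycle

import numpy as np
import pandas as pd

from .counts import SiteCountMatrix, site_index
from .genome import GenomeModel

__all__ = [
    "FRAGMENT_LENGTH",
    "CUT_OFFSET",
    "MethylationProfile",
    "InjectedDMRTruth",
    "plan_injections",
    "generate_methylation_profiles",
    "digest_genome",
    "simulate_reads",
    "simulate_site_counts",
    "simulate_expression",
]

#: LpnPI excises fragments of this many bases around a methylated CpG.
FRAGMENT_LENGTH = 32
#: The enzyme cuts this many bases downstream of the methylated C; by the
#: fragment convention [c-16, c+16) the C also sits 16 bases from the 5' end.
CUT_OFFSET = 16

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


@dataclass
class MethylationProfile:
    """Latent per-site, per-sample methylation fractions in [0, 1].

    ``frame`` is indexed by (chrom, pos) with one column per sample; the
    site set is shared across samples by construction.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("methylation fractions must lie in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns)

    def sample(self, sample_id: str) -> pd.Series:
        return self.frame[sample_id]


@dataclass
class InjectedDMRTruth:
    """Ground truth for one injected differential region."""

    chrom: str
    start: int
    end: int
    fold_change: float
    hyper_group: str
    site_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fold_change < 1:
            raise ValueError(f"fold change must be >= 1, got {self.fold_change}")
        if not self.start < self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")


def plan_injections(
    genome: GenomeModel,
    n_regions: int,
    fold_change: float = 1.5,
    n_sites: int = 5,
    hyper_group: "str | None" = None,
    groups: tuple[str, str] = ("S45F", "T41A"),
    min_gap_sites: int = 3,
    seed: int = 0,
) -> list[InjectedDMRTruth]:
    """Choose ``n_regions`` non-overlapping runs of ``n_sites`` adjacent
    LpnPI sites and mark them for injection at ``fold_change``.

    The hypermethylated group is ``hyper_group`` if given, otherwise drawn
    per region.  Regions are separated by at least ``min_gap_sites``
    intervening sites so injected effects never merge.
    """
    sites = genome.lpnpi_sites()
    rng = np.random.default_rng(seed)
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    eligible = []
    for i in range(len(sites) - n_sites + 1):
        if chroms[i] == chroms[i + n_sites - 1]:
            eligible.append(i)
    if not eligible:
        raise ValueError(f"no run of {n_sites} sites available for injection")
    rng.shuffle(eligible)
    taken: list[tuple[int, int]] = []
    out: list[InjectedDMRTruth] = []
    for i in eligible:
        if len(out) == n_regions:
            break
        lo, hi = i - min_gap_sites, i + n_sites + min_gap_sites
        if any(not (hi <= s or lo >= e) for s, e in taken):
            continue
        run = pos[i : i + n_sites]
        hyper = hyper_group or groups[int(rng.random() < 0.5)]
        out.append(
            InjectedDMRTruth(
                chrom=str(chroms[i]),
                start=int(run[0]),
                end=int(run[-1]) + 1,
                fold_change=fold_change,
                hyper_group=hyper,
                site_positions=[int(p) for p in run],
            )
        )
        taken.append((i, i + n_sites))
    if len(out) < n_regions:
        raise ValueError(
            f"could only place {len(out)} of {n_regions} injected regions"
        )
    out.sort(key=lambda t: (t.chrom, t.start))
    return out


def generate_methylation_profiles(
    genome: GenomeModel,
    sample_sheet: pd.DataFrame,
    injected: "list[InjectedDMRTruth] | None" = None,
    baseline_mean: float = 0.3,
    noise_sd: float = 0.05,
    site_sd: float = 0.1,
    group_column: str = "group",
    seed: int = 0,
) -> tuple[MethylationProfile, list[InjectedDMRTruth]]:
    """Per-sample methylation fractions with injected group differences.

    Each site gets a shared baseline ``baseline_mean * exp(site_sd * z)``
    (clipped to [0.01, 0.6] so fold changes up to ~2.7 survive the [0, 1]
    clamp); inside an injected region the hypermethylated group is scaled
    by sqrt(fold_change) and the other group by 1/sqrt(fold_change), so the
    group-mean ratio equals the requested fold change when noise is off.
    Per-sample Gaussian noise of sd ``noise_sd`` is added last and values
    are clipped to [0, 1].

    Returns the profile and the injected-truth list with site ids filled
    in.  Raises if an injected interval contains no LpnPI site.
    """
    if not 0 < baseline_mean < 1:
        raise ValueError(f"baseline_mean must be in (0, 1), got {baseline_mean}")
    groups = list(dict.fromkeys(sample_sheet[group_column]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    injected = list(injected or [])

    sites = genome.lpnpi_sites()
    idx = site_index(sites)
    n = len(sites)
    rng = np.random.default_rng(seed)
    site_base = np.clip(baseline_mean * np.exp(site_sd * rng.standard_normal(n)), 0.01, 0.6)

    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    factor = {g: np.ones(n) for g in groups}
    for t in injected:
        mask = (chrom_arr == t.chrom) & (pos_arr >= t.start) & (pos_arr < t.end)
        if not mask.any():
            raise ValueError(
                f"injected interval {t.chrom}:{t.start}-{t.end} contains no LpnPI site"
            )
        t.site_positions = [int(p) for p in pos_arr[mask]]
        if t.hyper_group not in groups:
            raise ValueError(
                f"injected hyper group {t.hyper_group!r} not in sample groups {groups}"
            )
        other = groups[1] if t.hyper_group == groups[0] else groups[0]
        r = np.sqrt(t.fold_change)
        factor[t.hyper_group] = factor[t.hyper_group].copy()
        factor[other] = factor[other].copy()
        factor[t.hyper_group][mask] *= r
        factor[other][mask] /= r

    data = {}
    for _, row in sample_sheet.iterrows():
        mean = site_base * factor[row[group_column]]
        noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
        data[row["sample_id"]] = np.clip(mean + noise, 0.0, 1.0)
    frame = pd.DataFrame(data, index=idx)
    return MethylationProfile(frame), injected


def digest_genome(
    genome: GenomeModel,
    profile: MethylationProfile,
    sample: str,
    seed: int = 0,
) -> pd.DataFrame:
    """LpnPI digestion of one sample: 32-bp fragments around methylated CpGs.

    Each LpnPI site is excised with probability equal to its methylation
    fraction.  A fragment spans [c-16, c+16) on the forward strand, so the
    cut falls 16 bp downstream of the methylated C and the C sits 16 bases
    from the fragment's 5' end.  Sites within 16 bases of a chromosome end
    are skipped.  Returns a (chrom, start, end, site) table.
    """
    meth = profile.sample(sample)
    rng = np.random.default_rng(seed)
    rows = []
    lengths = genome.chrom_lengths()
    chrom_level = meth.index.get_level_values("chrom").to_numpy()
    pos_level = meth.index.get_level_values("pos").to_numpy()
    vals = meth.to_numpy()
    for chrom, ln in lengths.items():
        mask = chrom_level == chrom
        pos = pos_level[mask]
        m = vals[mask]
        ok = (pos >= CUT_OFFSET) & (pos + CUT_OFFSET <= ln)
        emit = ok & (rng.random(pos.size) < m)
        for c in pos[emit]:
            rows.append((chrom, int(c) - CUT_OFFSET, int(c) + CUT_OFFSET, int(c)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "site"])


def simulate_reads(
    fragments: pd.DataFrame,
    genome: GenomeModel,
    read_length: int = 50,
    offset_jitter: tuple[int, int] = (13, 17),
    adapter_fill: str = DEFAULT_ADAPTER,
    seed: int = 0,
    read_prefix: str = "read",
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Single-end reads from digestion fragments, plus a truth table.

    Each fragment yields one read of exactly ``read_length`` nt.  The
    offset of the site's C from the read 5' end is drawn uniformly from
    ``offset_jitter`` (default [13, 17], the window the downstream filter
    accepts; widen it to exercise both passing and failing reads).  Genomic
    sequence outside the chromosome, and everything past the fragment's
    context, is filled from ``adapter_fill`` (cycled), mimicking adapter
    read-through on 32-bp inserts sequenced at 50 nt.

    Returns ``(records, truth)`` where records are (read_id, sequence)
    pairs and truth has one row per read: read_id, chrom, site, offset,
    read start.  ``read_length`` below 32 is rejected.
    """
    if read_length < FRAGMENT_LENGTH:
        raise ValueError(
            f"read_length must be >= {FRAGMENT_LENGTH}, got {read_length}"
        )
    lo, hi = offset_jitter
    if not (0 <= lo <= hi <= FRAGMENT_LENGTH):
        raise ValueError(f"offset_jitter must lie within [0, 32], got {offset_jitter}")
    rng = np.random.default_rng(seed)
    seqs = {c.name: c.sequence for c in genome.chromosomes}
    records: list[tuple[str, str]] = []
    truth_rows = []
    offsets = rng.integers(lo, hi + 1, size=len(fragments))
    for k, (row, off) in enumerate(zip(fragments.itertuples(index=False), offsets)):
        chrom_seq = seqs[row.chrom]
        c = int(row.site)
        off = int(off)
        start = c - off
        chars = []
        fill = cycle(adapter_fill)
        for j in range(start, start + read_length):
            # genomic bases only inside the excised fragment; everything
            # outside it is ligated adapter
            if row.start <= j < row.end:
                chars.append(chrom_seq[j])
            else:
                chars.append(next(fill))
        read_id = f"{read_prefix}_{k:07d}"
        records.append((read_id, "".join(chars)))
        truth_rows.append((read_id, row.chrom, c, off, start))
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "chrom", "site", "offset", "start"]
    )
    return records, truth


def write_fastq(records: list[tuple[str, str]], path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for read_id, seq in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_site_counts(
    profile: MethylationProfile,
    mean_depth: float = 30.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> SiteCountMatrix:
    """Per-site read counts without read-level simulation.

    The expected count at a site is ``mean_depth x methylation fraction``.
    Counts are negative binomial via a gamma-Poisson mixture with
    ``var = mu + dispersion * mu^2``; ``dispersion=0`` is exactly Poisson.
    """
    if mean_depth <= 0:
        raise ValueError(f"mean_depth must be positive, got {mean_depth}")
    if dispersion < 0:
        raise ValueError(f"dispersion must be non-negative, got {dispersion}")
    rng = np.random.default_rng(seed)
    mu = mean_depth * profile.frame.to_numpy()
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, dispersion * mu)
    else:
        lam = mu
    counts = rng.poisson(lam)
    frame = pd.DataFrame(counts, index=profile.frame.index, columns=profile.frame.columns)
    return SiteCountMatrix(frame)


def simulate_expression(
    probe_to_gene: pd.Series,
    groups: dict[str, list[str]],
    effect_genes: "dict[str, float] | None" = None,
    base_level: float = 100.0,
    cv: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic probe x sample expression matrix for the validation stage.

    ``probe_to_gene`` maps probe id -> gene symbol (several probes may map
    to one gene, as on the U133 Plus 2.0 array).  ``groups`` maps the two
    group labels to sample-id lists.  Genes in ``effect_genes`` are scaled
    by the given factor in the *first* group; all other genes are null.
    Values are log-normal around a per-probe baseline.
    """
    rng = np.random.default_rng(seed)
    effect_genes = effect_genes or {}
    (ga, samples_a), (gb, samples_b) = groups.items()
    samples = list(samples_a) + list(samples_b)
    sigma = np.sqrt(np.log1p(cv**2))
    data = np.empty((len(probe_to_gene), len(samples)))
    for i, (probe, gene) in enumerate(probe_to_gene.items()):
        probe_base = base_level * np.exp(rng.normal(0.0, 0.5))
        fc = effect_genes.get(gene, 1.0)
        mean_by_sample = [probe_base * fc] * len(samples_a) + [probe_base] * len(samples_b)
        data[i] = [m * np.exp(rng.normal(0.0, sigma)) for m in mean_by_sample]
    return pd.DataFrame(data, index=probe_to_gene.index, columns=samples)
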