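"""Synthetic genome model for MeD-seq simulations.

MeD-seq concentrates sequencing on methylated CpG sites via the
methylation-dependent restriction enzyme LpnPI.  Everything downstream of
the sequencer is defined relative to a genome: chromosome sequences, the
catalogue of LpnPI-recognizable sites (modelled here as CpG dinucleotides),
gene annotations with strand-aware TSS/TES, and CpG-island intervals.

All coordinates are 0-based, half-open.  Human-facing report tables convert
to 1-based inclusive at write time (see :mod:`medseqdmr.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Chromosome",
    "GeneAnnotation",
    "GenomeModel",
    "generate_genome",
    "locate_lpnpi_sites",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C = ord("C")
_G = ord("G")
_T = ord("T")


@dataclass
class Chromosome:
    """A named chromosome sequence; ``is_sex`` marks X/Y."""

    name: str
    sequence: str
    is_sex: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """A gene interval with strand-aware transcription start/end sites.

    On the + strand the TSS is the interval start and the TES the end; on
    the − strand the roles swap.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeModel:
    """Chromosomes plus gene and CpG-island annotation.

    The coordinate frame for the whole pipeline: LpnPI sites, fragments,
    reads, regions and DMRs all refer to these chromosomes.
    """

    chromosomes: list[Chromosome]
    genes: list[GeneAnnotation] = field(default_factory=list)
    cpg_islands: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = self.chrom_lengths()
        for g in self.genes:
            if g.chrom not in lengths:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > lengths[g.chrom]:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of {g.chrom} "
                    f"({g.end} > {lengths[g.chrom]})"
                )
        for chrom, start, end in self.cpg_islands:
            if chrom not in lengths:
                raise ValueError(f"CpG island on unknown chromosome {chrom}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError(f"CpG island {chrom}:{start}-{end} out of bounds")

    def chrom_lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def lpnpi_sites(self) -> pd.DataFrame:
        """All LpnPI sites genome-wide as a (chrom, pos) table.

        Rows are sorted by chromosome (in genome order) then position, the
        ordering every count matrix in the pipeline inherits.
        """
        frames = []
        for c in self.chromosomes:
            pos = locate_lpnpi_sites(c.sequence)
            frames.append(pd.DataFrame({"chrom": c.name, "pos": pos}))
        if not frames:
            return pd.DataFrame({"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=int)})
        return pd.concat(frames, ignore_index=True)


def locate_lpnpi_sites(sequence: str) -> list[int]:
    """Positions of the C of every CpG dinucleotide in ``sequence``.

    LpnPI recognition is modelled as any CpG; overlapping occurrences
    ("CGCG" -> [0, 2]) are all reported.  Returns a sorted, duplicate-free
    list; an empty sequence yields an empty list.
    """
    out: list[int] = []
    i = sequence.find("CG")
    while i != -1:
        out.append(i)
        i = sequence.find("CG", i + 1)
    return out


def _random_sequence(length: int, cpg_rate: float, rng: np.random.Generator) -> str:
    """Random chromosome sequence whose CG-dinucleotide frequency ~= cpg_rate.

    Background bases are drawn uniformly and any background CG is broken
    (the G after a C becomes T); CpGs are then planted at even offsets with
    per-candidate probability 2*cpg_rate, so the per-base CG rate is
    cpg_rate while plants can never overlap each other.
    """
    if length == 0:
        return ""
    arr = rng.choice(_BASES, size=length)
    if length > 1:
        bg = (arr[:-1] == _C) & (arr[1:] == _G)
        arr[1:][bg] = _T
        candidates = np.arange(0, length - 1, 2)
        plant = candidates[rng.random(candidates.size) < 2.0 * cpg_rate]
        arr[plant] = _C
        arr[plant + 1] = _G
    return arr.tobytes().decode("ascii")


def _place_genes(
    chrom_lengths: dict[str, int],
    n_genes: int,
    rng: np.random.Generator,
) -> list[GeneAnnotation]:
    # Non-overlapping by construction, each >= 2 kb so both the TSS window
    # and the gene body are non-empty; gaps leave room for intergenic DMRs.
    genes: list[GeneAnnotation] = []
    names = [n for n, ln in chrom_lengths.items() if ln >= 6000]
    if not names or n_genes == 0:
        return genes
    total = sum(chrom_lengths[n] for n in names)
    quota = {n: int(round(n_genes * chrom_lengths[n] / total)) for n in names}
    # rounding may drop/add a gene; pin the total
    diff = n_genes - sum(quota.values())
    quota[names[0]] += diff
    gid = 0
    for name in names:
        cursor = int(rng.integers(1500, 4000))
        placed = 0
        while placed < quota[name]:
            glen = int(rng.integers(2000, 8001))
            if cursor + glen + 1500 > chrom_lengths[name]:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneAnnotation(f"GENE{gid:04d}", name, strand, cursor, cursor + glen)
            )
            gid += 1
            placed += 1
            cursor += glen + int(rng.integers(1500, 6001))
    return genes


def _place_islands(
    chrom_lengths: dict[str, int],
    n_islands: int,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    islands: list[tuple[str, int, int]] = []
    names = [n for n, ln in chrom_lengths.items() if ln >= 2000]
    if not names or n_islands == 0:
        return islands
    weights = np.array([chrom_lengths[n] for n in names], dtype=float)
    weights /= weights.sum()
    for _ in range(n_islands):
        name = names[rng.choice(len(names), p=weights)]
        ilen = int(rng.integers(300, 1501))
        start = int(rng.integers(0, chrom_lengths[name] - ilen))
        islands.append((name, start, start + ilen))
    islands.sort()
    return islands


def generate_genome(
    lengths: "list[int] | dict[str, int]",
    cpg_rate: float = 0.05,
    n_genes: int = 20,
    n_islands: int = 10,
    sex_chrom_names: "set[str] | tuple[str, ...]" = (),
    seed: int = 0,
) -> GenomeModel:
    """Generate a deterministic multi-chromosome synthetic genome.

    Parameters
    ----------
    lengths
        Chromosome lengths in bases; either a list (chromosomes are named
        ``chr1..chrN``) or an explicit name -> length mapping.  Zero-length
        chromosomes are allowed and carry no sites.
    cpg_rate
        Target CG-dinucleotide frequency per base, in [0, 0.5].  Human
        genome-wide density is ~0.01 with CpG islands locally much denser;
        the default 0.05 keeps site counts high at desk-scale lengths.
    n_genes, n_islands
        Number of gene and CpG-island annotations to place.
    sex_chrom_names
        Chromosome names to flag as sex chromosomes.
    seed
        Seed for all randomness; identical calls are byte-identical.
    """
    if isinstance(lengths, dict):
        named = dict(lengths)
    else:
        named = {f"chr{i + 1}": int(ln) for i, ln in enumerate(lengths)}
    for name, ln in named.items():
        if ln < 0:
            raise ValueError(f"chromosome {name}: negative length {ln}")
    if not 0.0 <= cpg_rate <= 0.5:
        raise ValueError(f"cpg_rate must be in [0, 0.5], got {cpg_rate}")
    if n_genes < 0 or n_islands < 0:
        raise ValueError("n_genes and n_islands must be non-negative")

    rng = np.random.default_rng(seed)
    sex = set(sex_chrom_names)
    chromosomes = [
        Chromosome(name, _random_sequence(ln, cpg_rate, rng), is_sex=name in sex)
        for name, ln in named.items()
    ]
    genes = _place_genes(named, n_genes, rng)
    islands = _place_islands(named, n_islands, rng)
    return GenomeModel(chromosomes, genes, islands)
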