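# Methods

## The assay and its computational model

MeD-seq digests genomic DNA with *LpnPI*, a methylation-dependent
restriction enzyme that recognizes methylated CpG-containing sites and cuts
16 bp downstream, releasing 32-bp fragments that are sequenced as 50-nt
single-end reads. The computational consequence is twofold: (i) read depth
at a CpG site is proportional to its methylation level, so methylation is
quantified by counting reads per site; and (ii) a genuine digestion product
carries its CpG at a nearly fixed distance from the read end, which the
13–17 bp end-distance filter exploits to remove off-target reads.

We model *LpnPI* recognition as any CpG dinucleotide (one site per CpG, the
C's position on the forward strand). The enzyme's full degenerate motif is
narrower, but the choice only scales the site catalogue; every downstream
stage is exercised identically. A motif hook can be layered on
`locate_lpnpi_sites` if needed.

**Fragment convention.** A fragment is `[c − 16, c + 16)` for a site whose
C sits at position `c`: length exactly 32, the C 16 bases from the 5′ end
and 16 bases from the downstream cut. This is the simplest geometry
consistent with a 16-bp downstream cut and a 32-bp product, and it places
the canonical site offset (16) centrally inside the closed filter window
[13, 17]. Sites within 16 bases of a chromosome end cannot yield a full
fragment and are skipped.

**Filter bounds.** "Between 13 and 17 bp" is read inclusively on both ends,
measured from either read end to the site's C (3′ distance of a base at
5′-offset *o* in a read of length *L* is *L* − 1 − *o*). When a read holds
two in-window sites, the site with the smaller genomic position is
attributed; the alternative (random tie-break) changes nothing at realistic
site spacing and would break determinism.

## The statistical core

### Contingency structure

For each feature (site or region) the test pools read counts over the
samples of each group and forms

|        | in feature | rest of library |
|--------|-----------:|----------------:|
| group A | a | N_A − a |
| group B | c | N_B − c |

tested by Pearson chi-square with 1 df, without Yates continuity correction
(counts are large; the correction is available as an argument). Degenerate
tables (zero margin) are untestable and are skipped with p = 1. This
pooled construction makes library-size differences between groups implicit
and requires no per-sample replication model. Its known cost: biological
variation between samples (overdispersion) inflates the statistic, so the
test is anti-conservative on real cohorts — the calibration results below
hold under Poisson sampling, and the fold-change filter plus the per-sample
Mann–Whitney stage are the pragmatic guards the pipeline applies on top.
Covariate-adjusted or beta-binomial per-sample models are deliberately out
of scope.

### Sliding window and multiplicity

Region mode tests each annotated region and applies Benjamini–Hochberg
(default) or Bonferroni across regions at α = 0.05 on the adjusted value.

Window mode tests every site at an uncorrected seeding level
(`site_alpha` = 0.05), bins maximal runs of neighboring significant sites
(inter-site gap ≤ `max_gap` = 1,000 bases; a non-significant site breaks
the run; runs shorter than `min_sites` = 2 are dropped), then re-tests each
run on its pooled counts. Because candidate runs emerge from a genome-wide
scan over all sites, the correction family for the run-level p-values
defaults to the **number of sites tested**, not the number of runs
(`correction_family="sites"`). Correcting only over the handful of
candidate runs ignores the selection step and calls spurious DMRs under a
pure null — two adjacent sites each at p < 0.05 by chance pool to a
nominally impressive p in a family of ~10; in the site-sized family the
same run is correctly non-significant. With the site-sized family the null
false-call rate stays at the nominal level (measured: ≥ 90% of null seeds
produce zero calls) while fold-2, 5-site effects at 30× depth are still
recovered with sensitivity ≥ 0.9. `correction_family="candidates"` exposes
the narrower convention.

DMR spans run from the first site's position to the last site's position
+ 1 (half-open; report tables are 1-based inclusive).

### Fold change and orientation

A DMR's fold change is the ratio of group means of per-sample normalized
in-DMR counts (sites summed per sample, then averaged per group), larger
mean over smaller, with a pseudocount (default 0.5, in normalized units)
added to both means to stabilize near-zero regions. The group with the
larger mean is "+" (hypermethylated), the other "−"; exact ties give fold
change 1 and "=" for both. Swapping group labels therefore inverts every
status and leaves every fold change unchanged. Calls with fold change
< 1.5 are treated as not biologically differential, and sex-chromosome
records are excluded by exact canonical name (X, Y, chrX, chrY) — an alt
contig such as `17_GL383563v3_alt` is autosomal and retained.

### Normalization

Per-sample counts-per-million of the total filtered, site-assigned library.
Region-level values are scaled by the same per-sample factor (so region
columns do not re-sum to 10⁶). The normalization tag is recorded in output
metadata.

### Mann–Whitney stage

Two-sided everywhere. Exact p by enumeration when min(n, m) ≤ 8 with no
ties, otherwise the tie-corrected normal approximation with continuity
correction; the reported U is the smaller of the two rank-sum statistics.
Per-DMR tests compare per-sample normalized in-DMR counts between groups;
expression validation runs one test per probe (a gene may have several
probes), with the median and IQR pooled over both groups' samples, matching
the published table layout where a single summary column is printed per
probe.

### Clustering

"Supervised" clustering in this design means supervised *selection*: DMRs
are chosen by a group contrast, then all samples are clustered on those
DMRs without using labels. Input values are log2(CPM + 1), z-scored per
DMR (constant rows become zeros); samples are clustered with average
linkage on Euclidean distances by default (complete/ward and correlation
distance available). Cutting the tree into two clusters yields a purity
summary per covariate — the fraction of samples agreeing with their
cluster's majority level — used to ask whether mutation, sex, site or size
drives the structure. The size-extreme contrast defaults to ≤ 34 mm vs
> 87 mm (the cohort's quartile bounds); samples with missing size are
excluded and logged.

## The synthetic-data generator

The generator emulates the study's data at desk scale and carries explicit
ground truth; all randomness flows from one seed per operation, and every
operation is deterministic given it.

* **Genome** — background bases are uniform with background CGs broken,
  then CpGs are planted at even offsets with per-candidate probability
  2 × `cpg_rate`, so the realized CG-dinucleotide frequency matches
  `cpg_rate` (default 0.05 — denser than the genome-wide human average,
  giving ~5,000 sites per 100 kb so calibration experiments run in
  seconds). Genes (≥ 2 kb, non-overlapping, random strand) and CpG islands
  are placed with length-proportional allocation.
* **Cohort** — 14 S45F + 15 T41A samples by default, with sex, tumor-site,
  size and age marginals matching the published cohort (log-normal sizes
  from the reported medians/IQRs; three sizes blanked as missing).
* **Methylation** — per-site baseline `0.3 · exp(0.1 z)` shared across
  samples (clipped to [0.01, 0.6] so effects up to ~2.7-fold survive the
  [0, 1] clamp), per-sample Gaussian noise (sd 0.05). Injected regions
  scale the hypermethylated group by √FC and the other by 1/√FC, so the
  group-mean ratio equals the requested fold change exactly when noise is
  off — fold changes 1.5–2.7 mirror the published effect-size range.
* **Counts** — negative binomial via gamma–Poisson with
  var = μ + φμ², φ = 0.1 by default and Poisson at φ = 0; μ = depth ×
  methylation, depth 30× by default.
* **Reads** — one 50-nt read per fragment; the site's 5′ offset is drawn
  uniformly from `offset_jitter` (default [13, 17]; widen to generate
  filter-failing reads); bases outside the 32-bp fragment are adapter
  fill, emulating read-through on short inserts.

**What the generator does not model:** FFPE damage (deamination,
fragmentation), bisulfite chemistry, base-quality or adapter errors,
mappability structure, copy-number variation, or correlated methylation
beyond the injected regions. Passing tests therefore demonstrate the
correctness and calibration of the *computation* under its stated sampling
assumptions, not robustness to every artifact of archival tissue data.

## Calibration and recovery (what the suite establishes)

All statements below are computed by the test suite on seeded simulations;
problem sizes were chosen so each experiment completes in seconds.

* **Null calibration** (~5,000 Poisson sites, 14 vs 15 samples, 30×, 20
  seeds): per-site chi-square p-values are uniform (KS α = 0.01), ~5% of
  sites fall below 0.05, and ≥ 90% of seeds produce zero corrected DMR
  calls. Calibration is asserted under Poisson sampling (dispersion 0,
  noise 0) because that is the regime in which the pooled chi-square is
  exact; under the generator's overdispersed defaults the same statistic
  is expectedly anti-conservative (see above).
* **Recovery** (50 injected DMRs, fold 2.0, 5 sites, same conditions, 20
  seeds): sensitivity ≥ 0.9 at ≥ 50% reciprocal overlap, observed FDR
  ≤ 0.1 at BH 0.05, median recovered fold change within 15% of 2.0.
* **Size contrast** (6 + 6 size-extreme samples sharing a fold-2 signal
  over 20 regions): the 2-cut of the supervised clustering misplaces at
  most one sample.

## Numerical and interface choices

* Coordinates are 0-based half-open internally; report tables are 1-based
  inclusive; BED/bedGraph keep the native 0-based frame.
* The chi-square uses the closed-form `N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d))`
  vectorized over features (float64 throughout; verified against
  `scipy.stats.chi2_contingency` without correction).
* Benjamini–Hochberg is `statsmodels`' step-up implementation; the
  enlarged-family variant pads the step-up recursion with the uncounted
  tests (verified against a hand recursion).
* The published DMR-call fixture is ingested verbatim: the record with a
  blank fold change is assigned the table's declared inclusion floor
  (1.5, from the file's header directive) with a load-time warning, and
  the record with reversed coordinates is kept as printed and flagged —
  neither is corrected.
* TSS windows are not clipped at neighboring genes; overlapping regions
  each receive a site's counts (no exclusive assignment); a DMR
  overlapping both a TSS window and a gene body is labelled TSS.
* Genes shorter than 2 kb yield a TSS region only (the nominal body would
  sit inside the TSS window's reach); the omission is logged.

## Known limitations

* The pooled chi-square ignores per-sample replication; with real
  between-sample heterogeneity its raw DMR counts are inflated (the
  per-sample Mann–Whitney stage and the fold-change filter are the
  corrective lenses, mirroring the original analysis design).
* Alignment is out of scope: synthetic mode uses truth placement and
  real-data mode ingests pre-mapped positions. No BAM writing.
* The expression-validation stage is validated on synthetic matrices; the
  published expression p-values are shipped as a fixture for comparison,
  not re-derived from the external array data.
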