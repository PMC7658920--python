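import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medseqdmr import (
    DMR,
    DegenerateTableError,
    GroupComparison,
    adjust_pvalues,
    annotate_dmrs,
    chisq_2x2,
    compute_fold_change,
    filter_dmrs,
    generate_methylation_profiles,
    plan_injections,
    simulate_site_counts,
    sliding_window_dmrs,
)
from medseqdmr import test_regions as region_mode_test
from medseqdmr.counts import SiteCountMatrix, site_index
from medseqdmr.dmr import bin_significant_sites
from medseqdmr.regions import RegionCountMatrix, RegionDefinition


def site_matrix(chrom_pos, counts, samples):
    sites = pd.DataFrame(chrom_pos, columns=["chrom", "pos"])
    frame = pd.DataFrame(np.asarray(counts), index=site_index(sites), columns=samples)
    return SiteCountMatrix(frame)


class TestChiSquare:
    def test_proportional_table_is_null(self):
        stat, p = chisq_2x2(10, 90, 20, 180)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # margins give expected counts (20, 80, 20, 80); sum (O-E)^2/E = 12.5
        stat, _ = chisq_2x2(30, 70, 10, 90)
        assert stat == pytest.approx(12.5)

    def test_row_swap_symmetry(self):
        assert chisq_2x2(30, 70, 10, 90)[0] == pytest.approx(chisq_2x2(10, 90, 30, 70)[0])

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            chisq_2x2(0, 0, 5, 10)
        with pytest.raises(DegenerateTableError):
            chisq_2x2(0, 5, 0, 10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chisq_2x2(-1, 5, 5, 5)

    def test_agrees_with_scipy_contingency(self):
        rng = np.random.default_rng(48)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 500, size=4)
            stat, p = chisq_2x2(a, b, c, d)
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert stat == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


def bh_oracle(p):
    """Step-up recursion by hand."""
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestAdjustment:
    def test_single_p_unchanged(self):
        for method in ("bonferroni", "bh"):
            assert adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    def test_bh_step_up_example(self):
        q = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bonferroni_caps_at_one(self):
        assert np.allclose(adjust_pvalues([0.6, 0.7], "bonferroni"), [1.0, 1.0])

    def test_bh_matches_hand_recursion(self):
        rng = np.random.default_rng(49)
        p = rng.random(25)
        assert np.allclose(adjust_pvalues(p, "bh"), bh_oracle(p))

    def test_enlarged_family(self):
        p = np.array([0.001, 0.01, 0.04])
        q = adjust_pvalues(p, "bh", family_size=100)
        assert np.allclose(q, bh_oracle(np.concatenate([p, np.ones(97)]))[:3])
        qb = adjust_pvalues(p, "bonferroni", family_size=100)
        assert np.allclose(qb, np.minimum(p * 100, 1))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2], "bh")


class TestBinning:
    def test_gap_and_run_segmentation(self):
        pos = np.array([0, 100, 2000, 2100, 2200, 5000])
        sig = np.array([True, True, True, True, True, False])
        # gap 2000-100 > max_gap 1000 splits the run
        runs = bin_significant_sites(pos, sig, max_gap=1000, min_sites=2)
        assert runs == [(0, 1), (2, 4)]
        assert bin_significant_sites(pos, sig, max_gap=1000, min_sites=3) == [(2, 4)]

    def test_nonsignificant_site_breaks_run(self):
        pos = np.arange(0, 500, 100)
        sig = np.array([True, True, False, True, True])
        assert bin_significant_sites(pos, sig, 1000, 2) == [(0, 1), (3, 4)]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(50)
        for _ in range(50):
            pos = np.sort(rng.choice(20_000, size=60, replace=False))
            sig = rng.random(60) < 0.4
            max_gap, min_sites = 800, 2
            runs = bin_significant_sites(pos, sig, max_gap, min_sites)
            # brute force: walk the flags
            expected = []
            cur = []
            for i in range(60):
                if sig[i] and (not cur or pos[i] - pos[cur[-1]] <= max_gap):
                    cur.append(i)
                else:
                    if len(cur) >= min_sites:
                        expected.append((cur[0], cur[-1]))
                    cur = [i] if sig[i] else []
            if len(cur) >= min_sites:
                expected.append((cur[0], cur[-1]))
            assert runs == expected


class TestFoldChange:
    def make_norm(self, values_a, values_b):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [100]})
        frame = pd.DataFrame(
            [list(values_a) + list(values_b)],
            index=site_index(sites),
            columns=[f"a{i}" for i in range(len(values_a))]
            + [f"b{i}" for i in range(len(values_b))],
        )
        groups = GroupComparison(
            [f"a{i}" for i in range(len(values_a))],
            [f"b{i}" for i in range(len(values_b))],
        )
        return frame, groups

    def test_published_headline_ratio(self):
        # group means 26.8 vs 10.0, S45F larger -> fold change 2.68, "+ -"
        frame, groups = self.make_norm([26.8, 26.8], [10.0, 10.0])
        fc, status = compute_fold_change(("chr1", 0, 200), frame, groups, pseudocount=0)
        assert fc == pytest.approx(2.68)
        assert status == {"S45F": "+", "T41A": "-"}

    def test_tie_gives_unit_fold_change(self):
        frame, groups = self.make_norm([5.0], [5.0])
        fc, status = compute_fold_change(("chr1", 0, 200), frame, groups, pseudocount=0)
        assert fc == 1.0
        assert status == {"S45F": "=", "T41A": "="}

    def test_direct_ratio(self):
        frame, groups = self.make_norm([30.0], [20.0])
        fc, _ = compute_fold_change(("chr1", 0, 200), frame, groups, pseudocount=0)
        assert fc == pytest.approx(1.5)

    def test_orientation_flips_with_groups(self):
        frame, groups = self.make_norm([30.0, 32.0], [20.0, 18.0])
        fc1, s1 = compute_fold_change(("chr1", 0, 200), frame, groups)
        fc2, s2 = compute_fold_change(("chr1", 0, 200), frame, groups.swapped())
        assert fc1 == pytest.approx(fc2)
        assert s1["S45F"] == s2["S45F"] == "+"
        assert s1["T41A"] == s2["T41A"] == "-"


def make_dmr(chrom, fc, start=100, end=200):
    return DMR(chrom, start, end, 3, 10.0, 1e-4, 1e-3, "bh", fold_change=fc,
               status={"S45F": "+", "T41A": "-"})


class TestFilterDMRs:
    def test_threshold_one_is_identity(self):
        dmrs = [make_dmr("1", 1.2), make_dmr("2", 3.0)]
        assert filter_dmrs(dmrs, fc_threshold=1.0, exclude_sex=False) == dmrs

    def test_sex_chromosome_flag(self):
        dmrs = [make_dmr("chrX", 2.0), make_dmr("X", 2.0), make_dmr("7", 2.0),
                make_dmr("17_GL383563v3_alt", 2.0)]
        kept = filter_dmrs(dmrs, exclude_sex=True)
        assert [d.chrom for d in kept] == ["7", "17_GL383563v3_alt"]
        assert filter_dmrs(dmrs, exclude_sex=False) == dmrs

    def test_fold_change_threshold(self):
        dmrs = [make_dmr("1", 1.49), make_dmr("1", 1.5), make_dmr("1", float("nan"))]
        kept = filter_dmrs(dmrs, fc_threshold=1.5, exclude_sex=False)
        assert [d.fold_change for d in kept] == [1.5]


class TestAnnotate:
    @pytest.fixture()
    def regions(self):
        return [
            RegionDefinition("G1:TSS", "TSS", "chr1", 4000, 6000, "G1", "+"),
            RegionDefinition("G1:body", "gene_body", "chr1", 6000, 9000, "G1", "+"),
            RegionDefinition("CGI_0", "cpg_island", "chr1", 5500, 5800),
        ]

    def test_body_only_overlap(self, regions):
        d = make_dmr("chr1", 2.0, 7000, 7100)
        annotate_dmrs([d], regions)
        assert d.genes == ["G1"]
        assert d.position_label == "postTSS1KB-TES"
        assert not d.cpg_island

    def test_tss_takes_precedence(self, regions):
        d = make_dmr("chr1", 2.0, 5900, 6200)  # spans the TSS/body boundary
        annotate_dmrs([d], regions)
        assert d.position_label == "TSS"

    def test_intergenic_dmr(self, regions):
        d = make_dmr("chr1", 2.0, 100, 200)
        annotate_dmrs([d], regions)
        assert d.genes == [] and d.position_label == "none"

    def test_island_flag_is_separate(self, regions):
        d = make_dmr("chr1", 2.0, 5600, 5700)
        annotate_dmrs([d], regions)
        assert d.cpg_island and d.position_label == "TSS"

    def test_matches_brute_force_classification(self):
        rng = np.random.default_rng(51)
        regions = []
        for i in range(20):
            s = int(rng.integers(0, 50_000))
            cls = ["TSS", "gene_body", "cpg_island"][i % 3]
            gene = f"G{i}" if cls != "cpg_island" else ""
            regions.append(
                RegionDefinition(f"R{i}", cls, "chr1", s, s + int(rng.integers(100, 3000)), gene)
            )
        for _ in range(100):
            s = int(rng.integers(0, 52_000))
            d = make_dmr("chr1", 2.0, s, s + int(rng.integers(10, 2000)))
            annotate_dmrs([d], regions)
            overl = [r for r in regions if r.start < d.end and d.start < r.end]
            has_tss = any(r.region_class == "TSS" for r in overl)
            has_body = any(r.region_class == "gene_body" for r in overl)
            expected_label = "TSS" if has_tss else ("postTSS1KB-TES" if has_body else "none")
            assert d.position_label == expected_label
            assert set(d.genes) == {r.gene_id for r in overl if r.gene_id}
            assert d.cpg_island == any(r.region_class == "cpg_island" for r in overl)


class TestRegionMode:
    def region_matrix(self, counts, samples, n_regions):
        regions = [
            RegionDefinition(f"R{i}", "cpg_island", "chr1", i * 1000, i * 1000 + 500)
            for i in range(n_regions)
        ]
        frame = pd.DataFrame(counts, index=[r.region_id for r in regions], columns=samples)
        lib = frame.sum(axis=0) * 10  # regions hold a tenth of each library
        return RegionCountMatrix(frame, regions, pd.Series(5, index=frame.index), lib)

    def test_proportional_groups_give_no_candidates(self):
        counts = np.tile([[10, 10, 20, 20]], (6, 1))
        rm = self.region_matrix(counts, ["a1", "a2", "b1", "b2"],  6)
        groups = GroupComparison(["a1", "a2"], ["b1", "b2"])
        assert region_mode_test(rm, groups) == []

    def test_excess_region_detected(self):
        rng = np.random.default_rng(52)
        hits = 0
        for rep in range(100):
            base = rng.poisson(50 * 10, size=(8, 4))  # 10 sites at 50x
            base[0, :2] *= 3  # 3-fold excess in group A's first region
            rm = self.region_matrix(base, ["a1", "a2", "b1", "b2"], 8)
            groups = GroupComparison(["a1", "a2"], ["b1", "b2"])
            found = region_mode_test(rm, groups)
            if any(d.region_id == "R0" and d.q < 0.05 for d in found):
                hits += 1
        assert hits >= 95

    def test_candidates_subset_and_bonferroni_order(self):
        rng = np.random.default_rng(53)
        counts = rng.poisson(100, size=(10, 4))
        counts[1, :2] *= 2
        rm = self.region_matrix(counts, ["a1", "a2", "b1", "b2"], 10)
        groups = GroupComparison(["a1", "a2"], ["b1", "b2"])
        found = region_mode_test(rm, groups, method="bonferroni", alpha=0.2)
        ids = {r.region_id for r in rm.regions}
        for d in found:
            assert d.region_id in ids
            assert d.q >= d.p


class TestSlidingWindow:
    def make_counts(self, rng, n_sites=400, n_a=4, n_b=4, depth=30):
        chrom_pos = [("chr1", int(p)) for p in np.arange(n_sites) * 40]
        counts = rng.poisson(depth, size=(n_sites, n_a + n_b))
        samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        return chrom_pos, counts, samples

    def test_no_significant_sites_gives_empty_list(self):
        chrom_pos = [("chr1", p) for p in range(0, 400, 40)]
        counts = np.tile([[30, 30, 30, 30]], (10, 1))
        mat = site_matrix(chrom_pos, counts, ["a1", "a2", "b1", "b2"])
        groups = GroupComparison(["a1", "a2"], ["b1", "b2"])
        assert sliding_window_dmrs(mat, groups) == []

    def test_group_swap_flips_status_keeps_fold_change(self, genome_small, sheet, groups):
        truths = plan_injections(genome_small, 3, 2.0, 5, hyper_group="S45F", seed=54)
        profile, _ = generate_methylation_profiles(
            genome_small, sheet, truths, noise_sd=0.0, seed=55
        )
        mat = simulate_site_counts(profile, 30, dispersion=0.0, seed=56)
        fwd = sliding_window_dmrs(mat, groups)
        rev = sliding_window_dmrs(mat, groups.swapped())
        assert len(fwd) == len(rev) > 0
        for d1, d2 in zip(fwd, rev):
            assert (d1.chrom, d1.start, d1.end) == (d2.chrom, d2.start, d2.end)
            assert d1.fold_change == pytest.approx(d2.fold_change)
            assert d1.status == d2.status  # status is keyed by label, not position

    def test_invariant_to_prepended_empty_chromosome(self, genome_small, sheet, groups):
        truths = plan_injections(genome_small, 2, 2.5, 5, hyper_group="S45F", seed=57)
        profile, _ = generate_methylation_profiles(
            genome_small, sheet, truths, noise_sd=0.0, seed=58
        )
        mat = simulate_site_counts(profile, 30, dispersion=0.0, seed=59)
        base = sliding_window_dmrs(mat, groups)

        extra_sites = pd.DataFrame({"chrom": ["chr0"] * 5, "pos": range(0, 200, 40)})
        zeros = pd.DataFrame(
            0, index=site_index(extra_sites), columns=mat.counts.columns
        )
        stacked = SiteCountMatrix(pd.concat([zeros, mat.counts]))
        with_zero = sliding_window_dmrs(stacked, groups)
        assert [(d.chrom, d.start, d.end, d.n_sites) for d in base] == [
            (d.chrom, d.start, d.end, d.n_sites) for d in with_zero
        ]

    def test_unsorted_matrix_rejected(self):
        sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [50, 10]})
        frame = pd.DataFrame([[1], [2]], index=site_index(sites), columns=["s"])
        with pytest.raises(ValueError, match="unsorted"):
            SiteCountMatrix(frame)
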