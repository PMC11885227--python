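"""Monotone filtering, windows/runs, downstream genes and enrichment."""

import itertools

import numpy as np
import pytest
from scipy import stats

from cfnipt import (
    ChromSizes,
    GeneAnnotation,
    GenomicInterval,
    TierSet,
    differential_coverage,
    enrich,
    infer_list_size,
    map_downstream_genes,
    monotonic_filter,
    overlap_pct,
    window_runs,
)
from cfnipt.fetal_regions import GroupLibrary
from cfnipt.genomic_io import DepthTrack
from cfnipt.open_chromatin import DOWN, UP, CandidateBlock, _binom_two_sided
from cfnipt.synthetic_cohort import simulate_merged_depth


def _tiers(depth_rows, totals=None, ffs=(0.05, 0.10, 0.15, 0.20)):
    """Build a TierSet from a (4, n) depth matrix on one chromosome."""
    depth_rows = np.asarray(depth_rows)
    totals = totals or [1000] * 4
    libs = []
    for i in range(4):
        tr = DepthTrack({"chrA": depth_rows[i].astype(np.int64)},
                        total_reads=totals[i], mode="read_start")
        libs.append(GroupLibrary(f"T{i}", ffs[i], 2, tr, totals[i]))
    return TierSet(libs)


class TestMonotonicFilter:
    def test_examples(self):
        # per position (column): (4,3,2,1) down-kept, (1,3,2,4) mixed-dropped,
        # (5,4,4,1) tied-dropped, (1,2,3,4) up-kept
        tiers = _tiers(np.array([[4, 1, 5, 1], [3, 3, 4, 2], [2, 2, 4, 3], [1, 4, 1, 4]]))
        cand = monotonic_filter(tiers)["chrA"]
        assert cand.pos.tolist() == [0, 3]
        assert cand.direction.tolist() == [DOWN, UP]

    def test_mixed_ordering_dropped(self):
        tiers = _tiers(np.array([[1], [3], [2], [4]]))
        cand = monotonic_filter(tiers)["chrA"]
        assert cand.pos.size == 0

    def test_normalization_respected(self):
        # raw depths equal but totals differ -> normalised strictly decreasing
        tiers = _tiers(np.array([[6], [6], [6], [6]]),
                       totals=[1000, 2000, 4000, 8000])
        cand = monotonic_filter(tiers)["chrA"]
        assert cand.pos.tolist() == [0] and cand.direction.tolist() == [DOWN]

    def test_keep_fraction_matches_permutation_enumeration(self, rng):
        """Random distinct 4-tuples: keep fraction equals the exhaustive
        count of monotone orderings (2 of 24)."""
        n = 20_000
        depths = rng.permuted(np.tile(np.arange(1, 5), (n, 1)), axis=1).T
        tiers = _tiers(depths)
        kept = monotonic_filter(tiers)["chrA"].pos.size
        exhaustive = sum(1 for p in itertools.permutations(range(4))
                         if p == tuple(sorted(p)) or p == tuple(sorted(p, reverse=True)))
        assert exhaustive == 2
        p_keep = exhaustive / 24
        assert abs(kept / n - p_keep) < 3 * np.sqrt(p_keep * (1 - p_keep) / n)

    def test_tierset_validation(self):
        with pytest.raises(ValueError):
            _tiers(np.zeros((4, 1)), ffs=(0.05, 0.05, 0.15, 0.20))


class TestDifferentialCoverage:
    def _pair(self, low_counts, high_counts, t_low=1000, t_high=1000):
        mk = lambda arr, tot: GroupLibrary(
            "G", 0.1, 1, DepthTrack({"chrA": np.asarray(arr, dtype=np.int64)},
                                    tot, "read_start"), tot)
        return mk(low_counts, t_low), mk(high_counts, t_high)

    def test_equal_counts_null(self):
        low, high = self._pair([10], [10])
        df = differential_coverage(low, high)
        assert df["fold_change"].iloc[0] == pytest.approx(1.0)
        assert df["p_value"].iloc[0] == pytest.approx(1.0)

    def test_zero_vs_twenty_closed_form(self):
        low, high = self._pair([0], [20])
        df = differential_coverage(low, high)
        assert df["p_value"].iloc[0] == pytest.approx(2 * 0.5 ** 20, rel=1e-9)

    def test_double_tail_matches_scipy_at_half(self):
        for x, n in [(3, 10), (0, 20), (7, 9)]:
            ours = _binom_two_sided(np.array([x]), np.array([n]), 0.5)[0]
            ref = stats.binomtest(x, n, 0.5).pvalue
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_bh_step_up_hand_case(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_both_zero_dropped_and_logged(self):
        low, high = self._pair([0, 5], [0, 10])
        df = differential_coverage(low, high)
        assert len(df) == 1 and df.attrs["n_dropped"] == 1

    def test_position_subset(self):
        low, high = self._pair([1, 2, 3, 4], [1, 2, 3, 4])
        df = differential_coverage(low, high, {"chrA": np.array([1, 3])})
        assert df["pos"].tolist() == [1, 3]


def _brute_force_runs(positions, flank=12, min_windows=5):
    """Union of per-candidate windows via a literal per-base paint-and-scan."""
    if len(positions) == 0:
        return []
    hi = max(positions) + flank + 1
    paint = np.zeros(hi + 1, dtype=int)
    owners = [[] for _ in range(hi + 1)]
    for p in positions:
        for b in range(max(p - flank, 0), p + flank + 1):
            paint[b] = 1
            owners[b].append(p)
    runs = []
    b = 0
    while b <= hi:
        if paint[b]:
            s = b
            members = set()
            while b <= hi and paint[b]:
                members.update(owners[b])
                b += 1
            if len(members) >= min_windows:
                runs.append((max(min(members) - flank, 0), max(members) + flank + 1,
                             len(members)))
        else:
            b += 1
    return runs


class TestWindowRuns:
    def _cand(self, positions, direction=DOWN):
        pos = np.asarray(sorted(positions))
        return {"chrA": CandidateBlock("chrA", pos,
                                       np.full(pos.size, direction, dtype=np.int8))}

    def test_five_consecutive_positions(self):
        runs = window_runs(self._cand([100, 101, 102, 103, 104]))
        assert len(runs) == 1
        r = runs[0]
        assert (r.interval.start, r.interval.end, r.n_windows) == (88, 117, 5)

    def test_four_windows_discarded(self):
        assert window_runs(self._cand([100, 101, 102, 103])) == []

    def test_direction_filter(self):
        cand = self._cand([100, 101, 102, 103, 104], direction=UP)
        assert window_runs(cand, direction=DOWN) == []
        assert len(window_runs(cand, direction=UP)) == 1

    def test_restrict_to_regions(self):
        cand = self._cand(range(100, 110))
        runs = window_runs(cand, restrict_to=[GenomicInterval("chrA", 0, 50)])
        assert runs == []
        runs = window_runs(cand, restrict_to=[GenomicInterval("chrA", 0, 500)])
        assert len(runs) == 1

    def test_matches_bruteforce_scanner(self, rng):
        for _ in range(100):
            positions = np.unique(rng.integers(0, 400, rng.integers(1, 60)))
            runs = window_runs(self._cand(positions))
            got = [(r.interval.start, r.interval.end, r.n_windows) for r in runs]
            assert got == _brute_force_runs(positions.tolist())

    def test_count_non_increasing_in_min_windows(self, rng):
        positions = np.unique(rng.integers(0, 2000, 300))
        counts = [len(window_runs(self._cand(positions), min_windows=k))
                  for k in range(1, 10)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDownstreamGenes:
    def _gene(self, gid, chrom, tss, strand):
        body = (GenomicInterval(chrom, tss, tss + 1000, strand) if strand == "+"
                else GenomicInterval(chrom, tss - 999, tss + 1, strand))
        return GeneAnnotation(gid, gid, body, strand)

    def _run(self, chrom, start, end):
        from cfnipt.open_chromatin import WindowRun
        return WindowRun(GenomicInterval(chrom, start, end), 5, DOWN)

    def test_run_upstream_of_tss_collected(self):
        genes = [self._gene("G1", "chrA", 10_000, "+")]
        runs = [self._run("chrA", 9_400, 9_500)]  # 500 bp upstream
        assert map_downstream_genes(runs, genes) == ["G1"]

    def test_far_run_not_collected(self):
        genes = [self._gene("G1", "chrA", 60_000, "+")]
        runs = [self._run("chrA", 9_400, 9_500)]  # 50 kb away
        assert map_downstream_genes(runs, genes) == []

    def test_minus_strand_window(self):
        genes = [self._gene("Gm", "chrA", 10_000, "-")]
        assert map_downstream_genes([self._run("chrA", 10_100, 10_200)], genes) == ["Gm"]
        assert map_downstream_genes([self._run("chrA", 9_400, 9_500)], genes) == []

    def test_matches_bruteforce_all_pairs(self, rng):
        genes = [self._gene(f"G{i}", "chrA", int(t), "+" if i % 2 else "-")
                 for i, t in enumerate(rng.integers(2_000, 90_000, 30))]
        runs = [self._run("chrA", int(s), int(s) + 200)
                for s in rng.integers(0, 95_000, 40)]
        got = set(map_downstream_genes(runs, genes, max_distance=5_000))
        brute = set()
        for g in genes:
            tss = g.tss_pos
            lo, hi = ((tss - 5_000, tss) if g.strand == "+" else (tss + 1, tss + 5_001))
            for r in runs:
                if r.interval.start < hi and lo < r.interval.end:
                    brute.add(g.gene_id)
        assert got == brute


class TestNDRRecovery:
    """Planted TSS-proximal dips surface as down-with-ff runs."""

    TIER_FFS = (0.05, 0.10, 0.15, 0.20)

    @staticmethod
    def _sensitivity(runs, genome):
        hit = 0
        for w in genome.ndr_windows:
            if any(r.interval.chrom == w.chrom and r.interval.start < w.end
                   and w.start < r.interval.end for r in runs):
                hit += 1
        return hit / len(genome.ndr_windows)

    def test_noiseless_expected_tiers(self, genome):
        from cfnipt import expected_depth

        libs = []
        for ff in self.TIER_FFS:
            tr = expected_depth(genome, ff, 2e7)
            libs.append(GroupLibrary(f"E{ff}", ff, 1, tr, int(2e7)))
        runs = window_runs(monotonic_filter(TierSet(libs)), direction=DOWN)
        assert self._sensitivity(runs, genome) >= 0.9

    def test_stochastic_merged_tiers(self, genome):
        """Tiers of 1,000 pooled 2e5-read libraries (1/100 of the clinical
        tier depth) recover >= 80% of planted NDR loci."""
        rng = np.random.default_rng(2024)
        libs = []
        for ff in self.TIER_FFS:
            n_reads = 1000 * 200_000
            tr = simulate_merged_depth(genome, ff, n_reads, rng)
            libs.append(GroupLibrary(f"T{ff}", ff, 1000, tr, n_reads))
        runs = window_runs(monotonic_filter(TierSet(libs)), direction=DOWN)
        assert self._sensitivity(runs, genome) >= 0.8


class TestEnrichment:
    def test_table_arithmetic(self):
        assert overlap_pct(6, 1578) == pytest.approx(0.38022814, abs=5e-9)
        assert infer_list_size(6, 0.38022814) == 1578
        assert overlap_pct(65, 1578) == pytest.approx(4.11913815, abs=5e-9)

    def test_hypergeometric_exact_enumeration(self):
        # all 5 drawn genes inside a 5-gene term of a 20-gene background
        genes = [f"g{i}" for i in range(5)]
        rows = enrich(genes, {"T": genes}, background_size=20)
        from math import comb
        assert rows[0].p_value == pytest.approx(1 / comb(20, 5), rel=1e-12)
        assert rows[0].overlap_pct == 100.0

    def test_overlap_pct_consistency(self, rng):
        genes = [f"g{i}" for i in range(40)]
        terms = {f"T{j}": rng.choice(genes, rng.integers(2, 20), replace=False)
                 for j in range(6)}
        rows = enrich(genes, terms, background_size=200)
        for r in rows:
            assert r.overlap_pct * r.list_size / 100 == pytest.approx(r.gene_count)
            assert 0 <= r.gene_count <= min(r.list_size, r.background_count)

    def test_empty_term_skipped(self):
        rows = enrich(["a"], {"T0": [], "T1": ["a", "b"]}, background_size=10)
        assert [r.term_id for r in rows] == ["T1"]
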