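"""Stratified merging, per-base regression, region calling and the flank PWM."""

import numpy as np
import pytest

from cfnipt import (
    ChromSizes,
    GenomicInterval,
    SampleMeta,
    build_flank_pwm,
    call_fetal_regions,
    detect_tandem_repeat,
    fit_groups,
    fit_position,
    merge_groups,
    simulate_sample,
)
from cfnipt.fetal_regions import (
    GroupLibrary, PWM, PositionFit, PositionFits, _pack_positionfits,
)
from cfnipt.synthetic_cohort import FragmentSet, ReferenceTable
from cfnipt.genomic_io import DepthTrack, depth_from_starts


def _frag(chrom_starts, read_length=40):
    return FragmentSet({c: np.sort(np.asarray(v, dtype=np.int64))
                        for c, v in chrom_starts.items()}, read_length)


def _meta(i, ff, total=100):
    return SampleMeta(f"S{i}", total, "male", ff_chrY=ff)


class TestMergeGroups:
    def test_singleton_groups_in_ff_order(self, toy_sizes):
        samples = [(_frag({"chrA": [10 * i]}), _meta(i, ff))
                   for i, ff in enumerate([0.15, 0.05, 0.20, 0.10])]
        groups = merge_groups(samples, toy_sizes, 4)
        assert [g.mean_ff for g in groups] == [0.05, 0.10, 0.15, 0.20]
        assert all(g.n_samples == 1 for g in groups)

    def test_depth_conservation(self, toy_sizes, rng):
        samples = [(_frag({"chrA": rng.integers(0, 900, 30),
                           "chrB": rng.integers(0, 400, 10)}),
                    _meta(i, 0.05 + 0.01 * i, total=40))
                   for i in range(6)]
        groups = merge_groups(samples, toy_sizes, 2)
        member_total = sum(f.to_track(toy_sizes).total() for f, _ in samples)
        assert sum(g.track.total() for g in groups) == member_total
        assert sum(g.total_reads for g in groups) == 240

    def test_too_many_groups(self, toy_sizes):
        samples = [(_frag({"chrA": [0]}), _meta(0, 0.1))]
        with pytest.raises(ValueError):
            merge_groups(samples, toy_sizes, 2)

    def test_group_ffs_increase_on_cohort(self, genome):
        rng = np.random.default_rng(8)
        samples = [simulate_sample(genome, float(ff), "male", n_reads=5_000,
                                   rng=rng, sample_id=f"S{i}")
                   for i, ff in enumerate(rng.uniform(0.05, 0.20, 40))]
        groups = merge_groups(samples, genome.chrom_sizes, 10)
        ffs = [g.mean_ff for g in groups]
        assert all(a < b for a, b in zip(ffs, ffs[1:]))


class TestFitPosition:
    def test_exact_linear_fetal_locus(self):
        ffs = [0.05, 0.10, 0.15, 0.20]
        f = fit_position([10 * x for x in ffs], ffs)
        assert f.slope == pytest.approx(10.0)
        assert f.intercept == pytest.approx(0.0, abs=1e-12)
        assert f.rel_error == pytest.approx(0.0, abs=1e-9)

    def test_constant_depth_zero_slope(self):
        f = fit_position([5.0] * 4, [0.05, 0.10, 0.15, 0.20])
        assert f.slope == pytest.approx(0.0)
        assert f.rel_error == pytest.approx(0.0, abs=1e-12)
        assert f.evaluable

    def test_matches_normal_equations(self, rng):
        """OLS agrees with an independently coded normal-equations solve."""
        ffs = np.sort(rng.uniform(0.01, 0.3, 4))
        y = rng.uniform(1, 10, 4)
        f = fit_position(y, ffs)
        X = np.column_stack([np.ones(4), ffs])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert f.intercept == pytest.approx(beta[0])
        assert f.slope == pytest.approx(beta[1])

    def test_all_zero_flagged(self):
        f = fit_position([0.0] * 4, [0.05, 0.10, 0.15, 0.20])
        assert not f.evaluable

    def test_needs_increasing_ffs(self):
        with pytest.raises(ValueError):
            fit_position([1, 2, 3], [0.2, 0.1, 0.15])

    def test_vectorised_matches_scalar(self, rng):
        """fit_groups reproduces per-position fit_position on random tracks."""
        sizes = ChromSizes({"chrA": 50})
        ffs = [0.05, 0.10, 0.15, 0.20]
        groups = []
        for i, ff in enumerate(ffs):
            arr = rng.integers(0, 20, 50).astype(np.int32)
            tr = DepthTrack({"chrA": arr}, total_reads=1000, mode="read_start")
            groups.append(GroupLibrary(f"G{i}", ff, 1, tr, 1000))
        fits = fit_groups(groups, error_mode="max", scale=1000)["chrA"]
        for pos in range(50):
            depths = [g.track.data["chrA"][pos] for g in groups]  # scale==total
            ref = fit_position(depths, ffs, raw_depths=depths)
            assert fits.slope[pos] == pytest.approx(ref.slope, rel=1e-9, abs=1e-9)
            assert fits.evaluable[pos] == ref.evaluable
            if ref.evaluable:
                assert fits.rel_error[pos] == pytest.approx(ref.rel_error, abs=1e-9)
            assert fits.min_raw[pos] == ref.min_raw


def _mk_fits(qualify, chrom="chrA", mode="read_start", read_length=40):
    n = len(qualify)
    q = np.asarray(qualify, dtype=bool)
    return PositionFits(
        chrom, 0,
        slope=np.where(q, 1.0, -1.0),
        intercept=np.zeros(n),
        rel_error=np.where(q, 0.001, 0.5),
        evaluable=np.ones(n, dtype=bool),
        min_raw=np.full(n, 10.0),
        mode=mode, read_length=read_length,
    )


class TestCallRegions:
    def test_consecutive_run_single_interval(self):
        fits = {"chrA": _mk_fits([False] * 5 + [True] * 10 + [False] * 5)}
        rs = call_fetal_regions(fits)
        assert [(r.start, r.end) for r in rs.regions] == [(5, 15)]

    def test_one_bp_gap_splits(self):
        q = [True] * 4 + [False] + [True] * 4
        rs = call_fetal_regions({"chrA": _mk_fits(q)})
        assert [(r.start, r.end) for r in rs.regions] == [(0, 4), (5, 9)]

    def test_min_reads_and_slope_filters(self):
        fits = _mk_fits([True] * 10)
        fits.min_raw[3] = 1.0          # below the 2-read minimum
        fits.slope[7] = -2.0           # depth falling with ff
        rs = call_fetal_regions({"chrA": fits})
        assert [(r.start, r.end) for r in rs.regions] == [(0, 3), (4, 7), (8, 10)]

    def test_coverage_mode_trims_read_footprint(self):
        fits = _mk_fits([True] * 60, mode="coverage", read_length=40)
        rs = call_fetal_regions({"chrA": fits})
        assert [(r.start, r.end) for r in rs.regions] == [(0, 21)]

    def test_matches_bruteforce_scanner(self, rng):
        """Random qualify masks: identical to a position-by-position scanner."""
        for _ in range(20):
            q = rng.random(200) < 0.4
            rs = call_fetal_regions({"chrA": _mk_fits(q)})
            called = np.zeros(200, dtype=bool)
            for iv in rs.regions:
                called[iv.start:iv.end] = True
            assert np.array_equal(called, q)

    def test_scalar_fit_stream(self):
        fits = [PositionFit("chrA", p, 1.0, 0.0, 0.001, True, 5.0)
                for p in [3, 4, 5, 9, 10]]
        rs = call_fetal_regions(fits)
        assert [(r.start, r.end) for r in rs.regions] == [(3, 6), (9, 11)]


class TestPWM:
    def _ref_with(self, flanks):
        ref = ReferenceTable()
        for i, seq in enumerate(flanks):
            ref.add_block("chrA", i * 100, seq)
        return ref, [GenomicInterval("chrA", i * 100 + len(seq), i * 100 + len(seq) + 10)
                     for i, seq in enumerate(flanks)]

    def test_identical_flanks_indicator_columns(self):
        seq = "ACGT" * 5
        ref, regions = self._ref_with([seq, seq, seq])
        pwm = build_flank_pwm(regions, ref, flank=20)
        assert pwm.consensus == seq
        assert np.allclose(np.sort(pwm.matrix, axis=0)[-1], 1.0)

    def test_hand_counted_frequencies(self):
        ref, regions = self._ref_with(["AAAA", "AATA"])
        pwm = build_flank_pwm(regions, ref, flank=4)
        a, c, g, t = pwm.matrix[:, 2]
        assert (a, t) == (0.5, 0.5) and (c, g) == (0.0, 0.0)

    def test_columns_sum_to_one_and_duplicate_invariance(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(5)]
        ref, regions = self._ref_with(seqs)
        pwm = build_flank_pwm(regions, ref, flank=8)
        assert np.allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-12)
        ref2, regions2 = self._ref_with(seqs + seqs)
        pwm2 = build_flank_pwm(regions2, ref2, flank=8)
        assert pwm2.consensus == pwm.consensus

    def test_missing_flank_skipped_with_warning(self):
        ref, regions = self._ref_with(["ACGTACGT"])
        regions.append(GenomicInterval("chrB", 500, 510))  # no reference there
        with pytest.warns(UserWarning, match="skipped"):
            pwm = build_flank_pwm(regions, ref, flank=8)
        assert pwm.n_sequences == 1

    def test_planted_motif_consensus(self, rng):
        """Flanks with 'CGGAACGGAA' planted at offset 8 over random background
        reproduce the motif in the consensus at 8-17."""
        flanks = []
        for _ in range(30):
            s = list(rng.choice(list("ACGT"), 50))
            s[8:18] = list("CGGAACGGAA")
            flanks.append("".join(s))
        ref, regions = self._ref_with(flanks)
        pwm = build_flank_pwm(regions, ref, flank=50)
        assert pwm.consensus[8:18] == "CGGAACGGAA"


def _brute_force_repeats(s, unit_min=3, min_copies=2):
    out = []
    for u in range(unit_min, len(s) + 1):
        for i in range(len(s)):
            unit = s[i:i + u]
            if len(unit) < u:
                break
            copies = 0
            j = i
            while s[j:j + u] == unit:
                copies += 1
                j += u
            if copies >= min_copies and not (i >= u and s[i - u:i] == unit):
                out.append((unit, copies, i))
    return out


class TestTandemRepeat:
    def test_flank_motif_pattern(self):
        found = detect_tandem_repeat("AGCGGAACGGAACG")
        assert ("CGGAA", 2, 2 + 0) in [(u, c, o) for u, c, o in found] or \
               ("CGGAA", 2, 2) in found

    def test_degenerate_poly_a(self):
        found = detect_tandem_repeat("AAAAAA", unit_min=3)
        assert found == [("AAA", 2, 0)]

    def test_matches_bruteforce(self, rng):
        for _ in range(50):
            s = "".join(rng.choice(list("ACG"), 40))
            assert sorted(detect_tandem_repeat(s)) == sorted(_brute_force_repeats(s))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            detect_tandem_repeat("")
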