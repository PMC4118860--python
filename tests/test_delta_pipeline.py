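"""Delta-profile pipeline: quantile normalisation oracle, delta construction,
segmentation/annotation, Wilcoxon vs enumeration, overlap grouping,
label-swap equivariance and the noisy-pair exclusion rule."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pairedcna as pc
from pairedcna.core_io import PairRecord, PairTable, ProbeGrid, Segment, SegmentSet
from pairedcna.delta_pipeline import (
    DeltaParams,
    DeltaProfile,
    compare_subtype_counts,
    count_delta_segments,
    find_overlaps,
    make_delta,
    quantile_normalize_pair,
    run_delta_pipeline,
    segment_delta,
)


def line_grid(n, spacing=25_000, chrom="chr1"):
    return ProbeGrid([f"{chrom}_{i}" for i in range(n)], [chrom] * n,
                     np.arange(n) * spacing + spacing // 2)


def two_profiles(grid, a, b, make_profile):
    t = make_profile(grid, a, "P_T", "P", "tumour")
    l = make_profile(grid, b, "P_L", "P", "lnm")
    return t, l


class TestQuantileNormalization:
    def test_mean_of_sorted_values_oracle(self, make_profile):
        grid = line_grid(3)
        t, l = two_profiles(grid, [1.0, 2.0, 3.0], [4.0, 6.0, 8.0], make_profile)
        tn, ln = quantile_normalize_pair(t, l)
        np.testing.assert_allclose(tn.log2ratio, [2.5, 4.0, 5.5])
        np.testing.assert_allclose(ln.log2ratio, [2.5, 4.0, 5.5])

    def test_order_within_sample_preserved(self, make_profile):
        grid = line_grid(4)
        t, l = two_profiles(grid, [3.0, 1.0, 4.0, 2.0], [10.0, 40.0, 20.0, 30.0],
                            make_profile)
        tn, ln = quantile_normalize_pair(t, l)
        assert list(np.argsort(tn.log2ratio)) == list(np.argsort(t.log2ratio))
        assert list(np.argsort(ln.log2ratio)) == list(np.argsort(l.log2ratio))

    def test_identical_samples_unchanged(self, make_profile):
        grid = line_grid(6)
        x = [0.3, -0.1, 0.0, 0.0, 0.5, -0.2]  # includes ties
        t, l = two_profiles(grid, x, x, make_profile)
        tn, ln = quantile_normalize_pair(t, l)
        np.testing.assert_allclose(tn.log2ratio, x)
        np.testing.assert_allclose(ln.log2ratio, x)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 60))
    def test_sorted_outputs_identical_any_untied_input(self, seed, n):
        rng = np.random.default_rng(seed)
        grid = line_grid(n)
        a = rng.normal(size=n)  # continuous draws: ties have measure zero
        b = rng.normal(size=n)
        t = pc.CNProfile(grid, a, pc.SampleMeta("T", "P", "tumour", "TNBC"))
        l = pc.CNProfile(grid, b, pc.SampleMeta("L", "P", "lnm", "TNBC"))
        tn, ln = quantile_normalize_pair(t, l)
        np.testing.assert_allclose(np.sort(tn.log2ratio),
                                   np.sort(ln.log2ratio), atol=1e-12)

    def test_tied_inputs_stay_tied_and_match_up_to_tie_averaging(self):
        """With ties in one sample only, tied probes share one output value
        (the mean of the replacement values over the tied ranks); the two
        output distributions then agree up to that within-tie averaging."""
        grid = line_grid(4)
        a = np.array([0.0, 0.0, 1.0, 2.0])
        b = np.array([0.1, 0.2, 0.3, 0.4])
        t = pc.CNProfile(grid, a, pc.SampleMeta("T", "P", "tumour", "TNBC"))
        l = pc.CNProfile(grid, b, pc.SampleMeta("L", "P", "lnm", "TNBC"))
        tn, ln = quantile_normalize_pair(t, l)
        ref = (np.sort(a) + np.sort(b)) / 2
        np.testing.assert_allclose(ln.log2ratio, ref)  # untied sample exact
        assert tn.log2ratio[0] == tn.log2ratio[1] == pytest.approx(ref[:2].mean())
        np.testing.assert_allclose(tn.log2ratio[2:], ref[2:])

    def test_grid_mismatch_rejected(self, make_profile):
        t = make_profile(line_grid(4), np.zeros(4), "T", "P", "tumour")
        l = make_profile(line_grid(5), np.zeros(5), "L", "P", "lnm")
        with pytest.raises(ValueError, match="share one probe grid"):
            quantile_normalize_pair(t, l)


class TestMakeDelta:
    def test_identical_pair_all_zeros(self, make_profile):
        grid = line_grid(10)
        x = np.linspace(-1, 1, 10)
        t, l = two_profiles(grid, x, x, make_profile)
        delta = make_delta(t, l, "P")
        assert np.all(delta.values == 0.0)

    def test_lnm_private_event_visible(self, make_profile):
        grid = line_grid(100)
        base = np.zeros(100)
        lnm = base.copy()
        lnm[40:60] += 0.8
        t, l = two_profiles(grid, base, lnm, make_profile)
        delta = make_delta(t, l, "P")
        np.testing.assert_allclose(delta.values[40:60], 0.8)
        np.testing.assert_allclose(np.delete(delta.values, np.s_[40:60]), 0.0)

    def test_delta_mean_near_zero_after_normalization(self, small_params):
        grid, profiles, pairs, _ = pc.simulate_cohort(3, 3, small_params)
        by_id = {p.sample_id: p for p in profiles}
        for pr in pairs:
            tn, ln = quantile_normalize_pair(by_id[pr.tumour_id], by_id[pr.lnm_id])
            delta = make_delta(tn, ln, pr.patient_id)
            assert abs(delta.values.mean()) < 0.02


def _fast_dp(**kw):
    return DeltaParams(cbs=pc.CBSParams(n_perm_split=200, seed=0), **kw)


class TestSegmentDelta:
    def test_zero_delta_one_neutral_segment_per_chromosome(self, make_profile):
        p = pc.SimParams(n_chrom=2, chrom_length_bp=3_000_000,
                         probe_spacing_bp=25_000)
        grid = pc.make_toy_genome(p)
        t, l = two_profiles(grid, np.zeros(len(grid)), np.zeros(len(grid)),
                            make_profile)
        delta = segment_delta(make_delta(t, l, "P"), t, l, _fast_dp())
        assert len(delta.segments) == 2
        assert all(s.state == "neutral" for s in delta.segments)
        assert all(a.tumour_state == "neutral" and a.lnm_state == "neutral"
                   for a in delta.annotations)

    def test_private_event_detected_with_states(self, make_profile):
        """An LNM-private +0.8 event on top of a shared clonal backbone (so
        the two distributions match, the precondition for per-pair quantile
        normalisation) is recovered as one qualifying gain segment."""
        rng = np.random.default_rng(0)
        grid = line_grid(800)
        clone = np.zeros(800)
        clone[100:180] += 0.8  # shared gain
        clone[500:650] -= 0.6  # shared loss
        tum = clone + rng.normal(0, 0.1, 800)
        lnm = clone + rng.normal(0, 0.1, 800)
        lnm[300:350] += 0.8  # LNM-private gain
        t, l = two_profiles(grid, tum, lnm, make_profile)
        tn, ln = quantile_normalize_pair(t, l)
        delta = segment_delta(make_delta(tn, ln, "P"), tn, ln, _fast_dp())
        qual = delta.qualifying_segments()
        assert len(qual) == 1
        seg, ann = qual[0]
        assert seg.mean == pytest.approx(0.8, abs=0.25)
        assert abs(seg.start_idx - 300) <= 2 and abs(seg.end_idx - 350) <= 2
        assert ann.lnm_state == "gain" and ann.tumour_state == "neutral"

    def test_subthreshold_event_fails_threshold_flag(self, make_profile):
        rng = np.random.default_rng(1)
        grid = line_grid(400)
        tum = rng.normal(0, 0.03, 400)
        lnm = rng.normal(0, 0.03, 400)
        lnm[100:200] += 0.15  # clear step, below the 0.2 reporting bar
        t, l = two_profiles(grid, tum, lnm, make_profile)
        delta = segment_delta(make_delta(t, l, "P"), t, l, _fast_dp())
        found = [
            (s, a) for s, a in zip(delta.segments, delta.annotations)
            if 0.05 < abs(s.mean)
        ]
        assert found
        assert all(not a.passes_threshold for _, a in found)
        assert count_delta_segments(delta, _fast_dp())[0] == 0


class TestCounts:
    def _delta_with_segments(self, means_probes):
        grid = line_grid(200)
        segs, idx = [], 0
        for mean, n in means_probes:
            segs.append(Segment("chr1", idx * 25_000, (idx + n) * 25_000,
                                idx, idx + n, mean, n))
            idx += n
        d = DeltaProfile("P", grid, np.zeros(200),
                         SegmentSet("P", segs),
                         annotations=[None] * len(segs))
        return d

    def test_no_qualifying_segments(self):
        d = self._delta_with_segments([(0.05, 100), (-0.1, 100)])
        assert count_delta_segments(d, DeltaParams()) == (0, 0)

    def test_min_probe_filter_arithmetic(self):
        d = self._delta_with_segments(
            [(0.5, 30), (0.0, 100), (-0.4, 5), (0.01, 65)])
        assert count_delta_segments(d, DeltaParams()) == (2, 1)


def brute_force_ranksum_p(x, y):
    """Exact two-sided rank-sum p by enumeration of all C(n1+n2, n1)
    assignments of the pooled values to group 1."""
    pooled = np.array(list(x) + list(y))
    n1 = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    ws = [ranks[list(c)].sum()
          for c in itertools.combinations(range(len(pooled)), n1)]
    extreme = sum(abs(w - mu) >= abs(w_obs - mu) - 1e-12 for w in ws)
    return extreme / math.comb(len(pooled), n1)


class TestWilcoxon:
    def _res(self, x, y):
        counts, subtypes = {}, {}
        for i, v in enumerate(x):
            counts[f"T{i}"] = v
            subtypes[f"T{i}"] = "TNBC"
        for i, v in enumerate(y):
            counts[f"E{i}"] = v
            subtypes[f"E{i}"] = "ERpos"
        return compare_subtype_counts(counts, subtypes)

    def test_identical_groups_maximal_p(self):
        res = self._res([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_exact_p_point_one(self):
        res = self._res([5, 6, 7], [1, 2, 3])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)
        assert res.statistic == 15.0  # ranks 4+5+6

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 8), rng.integers(3, 8)
        # distinct values => exact path, no ties
        vals = rng.permutation(100)[: n1 + n2].astype(float)
        x, y = vals[:n1], vals[n1:]
        res = self._res(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_ranksum_p(x, y),
                                            abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match=">=2 patients"):
            self._res([1, 2, 3], [])


def _seg(chrom, lo_kb, hi_kb, mean, patient):
    n = max(1, (hi_kb - lo_kb) // 25)
    s = Segment(chrom, lo_kb * 1000, hi_kb * 1000, 0, n, mean, n)
    return patient, s


def _delta_from_segs(patient, segs, grid):
    return DeltaProfile(patient, grid, np.zeros(len(grid)),
                        SegmentSet(patient, segs),
                        annotations=[None] * len(segs))


class TestOverlaps:
    def _make(self, spec):
        """spec: list of (patient, chrom, lo_kb, hi_kb, mean)."""
        grid = line_grid(10)
        by_pat = {}
        for pat, chrom, lo, hi, mean in spec:
            n = max(1, (hi - lo) // 25)
            by_pat.setdefault(pat, []).append(
                Segment(chrom, lo * 1000, hi * 1000, 0, n, mean, n))
        return [_delta_from_segs(p, s, grid) for p, s in by_pat.items()]

    def test_different_chromosomes_no_groups(self):
        deltas = self._make([("P1", "chr1", 0, 500, 0.5),
                             ("P2", "chr2", 0, 500, 0.5)])
        assert find_overlaps(deltas, DeltaParams()) == []

    def test_opposite_signs_inconsistent_direction(self):
        deltas = self._make([("P1", "chr1", 0, 500, 0.5),
                             ("P2", "chr1", 250, 750, -0.5)])
        groups = find_overlaps(deltas, DeltaParams())
        assert len(groups) == 1
        g = groups[0]
        assert not g.consistent_direction
        assert (g.start_pos, g.end_pos) == (250_000, 500_000)

    def test_same_sign_consistent_direction(self):
        deltas = self._make([("P1", "chr1", 0, 500, 0.3),
                             ("P2", "chr1", 100, 600, 0.2),
                             ("P3", "chr1", 200, 700, 0.4)])
        groups = find_overlaps(deltas, DeltaParams())
        assert len(groups) == 1
        assert groups[0].consistent_direction
        assert groups[0].n_patients == 3

    def test_below_candidate_threshold_ignored(self):
        deltas = self._make([("P1", "chr1", 0, 500, 0.05),
                             ("P2", "chr1", 0, 500, 0.5)])
        assert find_overlaps(deltas, DeltaParams()) == []

    def test_transitive_chaining_vs_pairwise_mode(self):
        # A overlaps B, B overlaps C, A does not overlap C
        spec = [("P1", "chr1", 0, 300, 0.5), ("P2", "chr1", 200, 600, 0.5),
                ("P3", "chr1", 500, 900, 0.5)]
        chained = find_overlaps(self._make(spec), DeltaParams())
        assert len(chained) == 1 and chained[0].n_patients == 3
        pairwise = find_overlaps(self._make(spec),
                                 DeltaParams(chain_overlaps=False))
        assert len(pairwise) == 2


class TestPipeline:
    def test_identical_cohort_null_end_to_end(self, small_params, make_profile):
        """tumour == LNM for every pair: zero qualifying segments, no
        overlaps, Wilcoxon p == 1 on the all-zero counts."""
        grid = pc.make_toy_genome(small_params)
        rng = np.random.default_rng(0)
        profiles = []
        for i in range(4):
            x = rng.normal(0, 0.1, len(grid))
            st = "TNBC" if i < 2 else "ERpos"
            profiles.append(make_profile(grid, x, f"P{i}_T", f"P{i}", "tumour", st))
            profiles.append(make_profile(grid, x, f"P{i}_L", f"P{i}", "lnm", st))
        pairs = PairTable.from_samples([p.meta for p in profiles])
        rep = run_delta_pipeline(profiles, pairs, _fast_dp())
        assert (rep.counts["n_segments"] == 0).all()
        assert rep.overlaps == []
        assert rep.wilcoxon.p_value == pytest.approx(1.0)

    def test_label_swap_equivariance(self, make_profile):
        """Swapping tumour/LNM negates the delta, preserves |means| and
        counts, and flips overlap directions."""
        rng = np.random.default_rng(4)
        grid = line_grid(400)
        tum = rng.normal(0, 0.1, 400)
        lnm = rng.normal(0, 0.1, 400)
        lnm[100:160] += 0.6
        t, l = two_profiles(grid, tum, lnm, make_profile)
        dp = _fast_dp()

        tn, ln = quantile_normalize_pair(t, l)
        fwd = segment_delta(make_delta(tn, ln, "P"), tn, ln, dp)
        ln2, tn2 = quantile_normalize_pair(l, t)
        rev = segment_delta(make_delta(ln2, tn2, "P"), ln2, tn2, dp)

        np.testing.assert_allclose(rev.values, -fwd.values, atol=1e-12)
        f = sorted(fwd.segments, key=lambda s: s.start_idx)
        r = sorted(rev.segments, key=lambda s: s.start_idx)
        assert [(s.start_idx, s.end_idx) for s in f] == \
            [(s.start_idx, s.end_idx) for s in r]
        np.testing.assert_allclose([s.mean for s in f],
                                   [-s.mean for s in r], atol=1e-12)
        assert count_delta_segments(fwd, dp) == count_delta_segments(rev, dp)

    def test_noisy_pair_flagged_and_excluded(self, small_params):
        p = pc.SimParams(**{**small_params.__dict__, "seed": 13})
        grid, profiles, pairs, _ = pc.simulate_cohort(
            3, 3, p, noisy_patients={"ER02": "lnm"})
        rep = run_delta_pipeline(profiles, pairs, _fast_dp())
        assert rep.excluded == ["ER02"]
        row = rep.counts.set_index("patient_id").loc["ER02"]
        assert row["noise_sd"] > 3 * rep.counts["noise_sd"].median()
        assert all(pid != "ER02"
                   for g in rep.overlaps for pid, _, _ in g.members)

    def test_subtype_divergence_contrast_detected(self):
        """TNBC pairs receiving ~3x the LNM-private divergence of ER+ pairs
        yield a significant subtype difference in delta-segment counts."""
        base = dict(n_chrom=1, chrom_length_bp=20_000_000,
                    probe_spacing_bp=25_000, noise_sd=0.1,
                    private_event_length_bp=(750_000, 1_500_000))
        sig = 0
        n_cohorts = 5
        for seed in range(n_cohorts):
            profiles, metas = [], []
            rng_seed = 100 + seed
            # TNBC pairs: 3 events each; ER+: 1 event each
            for subtype, n_events, tag in (("TNBC", 3, "T"), ("ERpos", 1, "E")):
                p = pc.SimParams(**base, p_private_lnm_event=1.0,
                                 p_private_tumour_event=0.0, seed=rng_seed)
                grid = pc.make_toy_genome(p)
                for i in range(8):
                    rng = np.random.default_rng((rng_seed, ord(tag), i))
                    clone, _ = pc.simulate_clone(grid, subtype, p, rng)
                    tum = clone + rng.normal(0, p.noise_sd, len(grid))
                    lnm = clone.copy()
                    for _ in range(n_events):
                        ev = pc.synthetic_data._draw_private_event(grid, p, rng)
                        amp = np.sign(ev.amplitude) * max(abs(ev.amplitude), 0.5)
                        lnm[ev.start_idx:ev.end_idx] += amp
                    lnm = lnm + rng.normal(0, p.noise_sd, len(grid))
                    pid = f"{tag}{i}"
                    mt = pc.SampleMeta(f"{pid}_T", pid, "tumour", subtype)
                    ml = pc.SampleMeta(f"{pid}_L", pid, "lnm", subtype)
                    profiles += [pc.CNProfile(grid, tum, mt),
                                 pc.CNProfile(grid, lnm, ml)]
                    metas += [mt, ml]
            pairs = PairTable.from_samples(metas)
            rep = run_delta_pipeline(profiles, pairs, _fast_dp())
            tn = rep.counts[rep.counts.subtype == "TNBC"]["n_segments"]
            er = rep.counts[rep.counts.subtype == "ERpos"]["n_segments"]
            assert tn.mean() > er.mean()
            sig += rep.wilcoxon.p_value < 0.05
        assert sig >= 4
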