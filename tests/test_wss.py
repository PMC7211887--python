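"""Window-based SNV similarity: windowing, QC gates, scoring, calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_wss
from strainmosaic import (
    DepthTrack,
    SNVProfile,
    WSSParams,
    classify_pair,
    make_windows,
    pair_qc,
    window_retained,
    window_similarity,
    wss_score,
)
from strainmosaic.synthetic_data import drift_strain, mutate_strain, simulate_pileup
from strainmosaic.ingest import call_consensus_snvs
from strainmosaic.wss import Window


def _profile(calls, sample="s", species="sp"):
    return SNVProfile(sample, species, calls, {p: 10 for p in calls})


def _track(depth):
    return DepthTrack("sp", np.asarray(depth))


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length,size,expected",
        [
            (2500, 1000, [(0, 1000), (1000, 2000), (2000, 2500)]),
            (1000, 1000, [(0, 1000)]),
            (1, 1000, [(0, 1)]),
        ],
    )
    def test_tiling_examples(self, length, size, expected):
        windows = make_windows(length, size)
        assert [(w.start, w.end) for w in windows] == expected

    def test_million_bp_gives_thousand_windows(self):
        assert len(make_windows(1_000_000, 1000)) == 1000

    @given(length=st.integers(1, 50_000), size=st.integers(1, 5000))
    @settings(max_examples=60, deadline=None)
    def test_windows_partition_reference(self, length, size):
        windows = make_windows(length, size)
        assert windows[0].start == 0 and windows[-1].end == length
        for prev, cur in zip(windows, windows[1:]):
            assert prev.end == cur.start
        assert all(w.length <= size for w in windows)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            make_windows(0, 1000)


class TestPairQC:
    def _depth(self, n_covered, total_sum, L=1000):
        d = np.zeros(L, dtype=int)
        if n_covered:
            d[:n_covered] = total_sum // n_covered
            d[0] += total_sum - (total_sum // n_covered) * n_covered
        return _track(d)

    def test_breadth_just_below_threshold_fails(self):
        low = self._depth(290, 5000)  # breadth 0.29
        good = self._depth(1000, 5000)
        qc = pair_qc(low, good)
        assert not qc.passed and qc.reason == "coverage"

    def test_mean_depth_just_below_threshold_fails(self):
        shallow = self._depth(1000, 3400)  # mean 3.4
        good = self._depth(1000, 5000)
        qc = pair_qc(shallow, good)
        assert not qc.passed and qc.reason == "depth"

    def test_exact_thresholds_pass(self):
        boundary = self._depth(300, 3500)  # breadth 0.30, mean 3.5
        qc = pair_qc(boundary, boundary)
        assert qc.passed

    def test_generous_coverage_passes(self):
        good = self._depth(1000, 20_000)
        assert pair_qc(good, good).passed


class TestWindowRetention:
    def _window(self, length=1000):
        return Window("sp", 0, length, 0)

    def test_501_low_bases_drops_window(self):
        d = np.full(1000, 10)
        d[:501] = 4
        retained, low_a, _ = window_retained(self._window(), _track(d), _track(np.full(1000, 10)))
        assert not retained and low_a == 501

    def test_exactly_half_low_retains(self):
        d = np.full(1000, 10)
        d[:500] = 4
        retained, *_ = window_retained(self._window(), _track(d), _track(np.full(1000, 10)))
        assert retained

    def test_either_sample_failing_drops(self):
        good = _track(np.full(1000, 10))
        bad = np.full(1000, 10)
        bad[:600] = 0
        assert not window_retained(self._window(), good, _track(bad))[0]

    def test_partial_terminal_window_uses_own_length(self):
        w = Window("sp", 0, 100, 0)
        d = np.full(100, 10)
        d[:51] = 2  # 51/100 > 50%
        assert not window_retained(w, _track(d), _track(np.full(100, 10)))[0]


class TestWindowSimilarity:
    def test_identical_profiles_fully_similar(self):
        a = _profile({10: "A", 500: "G"})
        union, conc, sim = window_similarity(a, a, Window("sp", 0, 1000, 0))
        assert (union, conc, sim) == (2, 2, 1.0)

    def test_hand_enumerated_half_similarity(self):
        a = _profile({10: "T", 500: "G"})
        b = _profile({10: "T"})
        union, conc, sim = window_similarity(a, b, Window("sp", 0, 1000, 0))
        assert (union, conc, sim) == (2, 1, 0.5)

    def test_empty_union_counts_as_one(self):
        a = _profile({})
        union, conc, sim = window_similarity(a, a, Window("sp", 0, 1000, 0))
        assert (union, conc, sim) == (0, 0, 1.0)

    def test_discordant_alt_bases_not_concordant(self):
        a = _profile({10: "T"})
        b = _profile({10: "G"})
        union, conc, sim = window_similarity(a, b, Window("sp", 0, 1000, 0))
        assert (union, conc, sim) == (1, 0, 0.0)


class TestWssScore:
    def test_two_window_toy_mean(self):
        # window 0: sim 1.0 (identical call); window 1: sim 0.5
        a = _profile({10: "T", 1010: "G", 1500: "C"})
        b = _profile({10: "T", 1010: "G"})
        depth = _track(np.full(2000, 10))
        res = wss_score(a, b, depth, depth)
        assert res.score == pytest.approx(75.0)
        assert res.n_windows_retained == 2

    def test_qc_failure_gives_no_score(self):
        a = _profile({})
        depth = _track(np.zeros(1000, dtype=int))
        res = wss_score(a, a, depth, depth)
        assert res.score is None and res.call == "no_call"
        assert not res.qc.passed

    def test_all_windows_low_depth_gives_no_score(self):
        a = _profile({})
        d = np.full(1000, 4)  # passes mean-depth 3.5 but every base < 5
        res = wss_score(a, a, _track(d), _track(d))
        assert res.qc.passed and res.n_windows_retained == 0 and res.score is None

    def test_empty_union_drop_policy(self):
        # one window with variants (sim 0.5), one empty-union window
        a = _profile({10: "T", 500: "G"})
        b = _profile({10: "T"})
        depth = _track(np.full(2000, 10))
        keep = wss_score(a, b, depth, depth, params=WSSParams(empty_union_policy="one"))
        drop = wss_score(a, b, depth, depth, params=WSSParams(empty_union_policy="drop"))
        assert keep.score == pytest.approx(75.0)
        assert drop.score == pytest.approx(50.0)

    def test_symmetry_and_self_identity(self, small_reference, small_strain):
        pu_a, dt_a = simulate_pileup(small_strain, 15, base_error_rate=0.002, seed=1)
        other = mutate_strain(small_reference, 0.005, seed=99, lineage_id="B")
        pu_b, dt_b = simulate_pileup(other, 15, base_error_rate=0.002, seed=2)
        prof_a = call_consensus_snvs(pu_a, small_reference, "a")
        prof_b = call_consensus_snvs(pu_b, small_reference, "b")
        assert wss_score(prof_a, prof_a, dt_a, dt_a).score == 100.0
        ab = wss_score(prof_a, prof_b, dt_a, dt_b).score
        ba = wss_score(prof_b, prof_a, dt_b, dt_a).score
        assert ab == ba

    def test_mean_score_degrades_with_divergence(self, small_reference):
        # over >=50 pairs per level, mean WSS is non-increasing in drift
        levels = [0.0, 0.001, 0.005, 0.01]
        means = []
        for li, d in enumerate(levels):
            scores = []
            for rep in range(50):
                base = mutate_strain(small_reference, 0.005, seed=1000 + rep)
                other = drift_strain(base, d, seed=2000 + 97 * li + rep) if d else base
                pu_a, dt_a = simulate_pileup(base, 15, base_error_rate=0.001, seed=3000 + rep)
                pu_b, dt_b = simulate_pileup(other, 15, base_error_rate=0.001, seed=4000 + 97 * li + rep)
                res = wss_score(
                    call_consensus_snvs(pu_a, small_reference, "a"),
                    call_consensus_snvs(pu_b, small_reference, "b"),
                    dt_a,
                    dt_b,
                )
                scores.append(res.score)
            means.append(np.mean(scores))
        assert all(m1 >= m2 for m1, m2 in zip(means, means[1:]))

    def test_matches_brute_force_oracle_randomized(self, rng):
        for _ in range(40):
            L = int(rng.integers(1000, 5001))
            depth_a = rng.poisson(rng.uniform(2, 12), L)
            depth_b = rng.poisson(rng.uniform(2, 12), L)
            calls_a = {
                int(p) + 1: "ACGT"[rng.integers(4)]
                for p in rng.choice(L, size=int(rng.integers(0, 40)), replace=False)
            }
            calls_b = {
                int(p) + 1: "ACGT"[rng.integers(4)]
                for p in rng.choice(L, size=int(rng.integers(0, 40)), replace=False)
            }
            res = wss_score(
                _profile(calls_a, "a"), _profile(calls_b, "b"),
                _track(depth_a), _track(depth_b),
            )
            expected = brute_wss(calls_a, calls_b, depth_a, depth_b)
            if expected is None:
                assert res.score is None
            else:
                assert res.score == pytest.approx(expected, abs=1e-9)

    @given(
        breadth_frac=st.floats(0.25, 0.35),
        mean_target=st.floats(3.0, 4.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_no_score_ever_leaks_past_qc(self, breadth_frac, mean_target):
        # fuzz depth tracks around the QC boundaries
        L = 2000
        n_cov = int(round(breadth_frac * L))
        per_base = max(1, int(round(mean_target * L / max(n_cov, 1))))
        d = np.zeros(L, dtype=int)
        d[:n_cov] = per_base
        track = _track(d)
        res = wss_score(_profile({}), _profile({}), track, track)
        qc = pair_qc(track, track)
        assert (res.score is not None) == (qc.passed and res.n_windows_retained >= 1)


class TestClassification:
    def _result(self, score):
        a = _profile({})
        depth = _track(np.full(1000, 10))
        res = wss_score(a, a, depth, depth)
        res.score = score
        return res

    def test_above_cutoff_related(self):
        assert classify_pair(self._result(85.0), 80.0).call == "related"

    def test_exactly_at_cutoff_unrelated(self):
        assert classify_pair(self._result(80.0), 80.0).call == "unrelated"

    def test_below_cutoff_unrelated(self):
        assert classify_pair(self._result(60.0), 80.0).call == "unrelated"

    def test_missing_cutoff_no_call(self):
        assert classify_pair(self._result(95.0), None).call == "no_call"
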