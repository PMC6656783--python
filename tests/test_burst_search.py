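"""Burst detection, thresholding, E*/S and ES histograms."""
import numpy as np
import pytest

from alexburst import (BurstSearchParams, BurstSet, PhotonStream,
                       burst_search, compute_es, es_histogram,
                       select_species, threshold_bursts)
from alexburst.simulate import SimConfig, SimSpecies, simulate_photon_stream

from _oracles import brute_burst_search, brute_counts, random_test_stream


def _stream(ts, ch, period=50):
    ts = np.asarray(ts, dtype=np.int64)
    ch = np.asarray(ch, dtype=np.uint8)
    return PhotonStream(ts, ch, period)


class TestSearchBasics:
    def test_empty_stream_gives_no_bursts(self):
        s = _stream([], [])
        assert len(burst_search(s)) == 0

    def test_hand_built_single_burst(self):
        # ~30 Dex + ~30 Aex photons interleaved within 400 us, flanked by
        # sparse background (1 photon / 10 ms) -> exactly one burst with
        # all 60 photons
        burst_ts = 1_000_000 + np.arange(60) * 6   # spans 354 us
        bg_before = np.arange(0, 990_000, 10_000)
        bg_after = np.arange(1_010_000, 2_000_000, 10_000)
        ts = np.concatenate([bg_before, burst_ts, bg_after])
        ch = np.zeros(ts.size, dtype=np.uint8)
        s = _stream(np.sort(ts), ch)
        # both phases well represented inside the dense region
        dense = (s.timestamps_us >= 1_000_000) & (s.timestamps_us < 1_000_400)
        assert 20 <= s.excitation[dense].sum() <= 40
        out = burst_search(s, BurstSearchParams(mode="dual-color"))
        assert len(out) == 1
        assert out.total_photons[0] == 60

    def test_uniform_background_no_bursts(self):
        # 100 photons/s for 10 s: ~0.05 photons per 500-us window << M
        rng = np.random.default_rng(1)
        ts = np.sort(rng.integers(0, 10_000_000, size=1000))
        s = _stream(ts, rng.integers(0, 2, size=1000))
        assert len(burst_search(s)) == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["all-photon", "dual-color"])
    def test_matches_brute_force_on_random_streams(self, mode):
        rng = np.random.default_rng(99)
        params = BurstSearchParams(mode=mode)
        for _ in range(25):
            ts, ch = random_test_stream(rng)
            s = _stream(ts, ch)
            exc = s.excitation
            got = burst_search(s, params)
            want = brute_burst_search(ts.tolist(), exc.tolist(),
                                      params.M, params.T, params.L, mode)
            assert len(got) == len(want)
            for row, ref in zip(got.df.itertuples(), want):
                assert row.start_us == ref["start"]
                assert row.end_us == ref["end"]
                counts = brute_counts(ts.tolist(), exc.tolist(),
                                      ch.tolist(), ref)
                for key, val in counts.items():
                    assert getattr(row, key) == val


class TestSearchProperties:
    def _sim_stream(self, seed):
        cfg = SimConfig(species=[SimSpecies("da", fret_e=0.5)],
                        duration_s=5.0, seed=seed)
        return simulate_photon_stream(cfg)[0]

    def test_dual_color_intervals_subset_of_all_photon(self):
        s = self._sim_stream(21)
        dual = burst_search(s, BurstSearchParams(mode="dual-color"))
        allp = burst_search(s, BurstSearchParams(mode="all-photon"))
        for row in dual.df.itertuples():
            contained = ((allp.df.start_us <= row.start_us)
                         & (allp.df.end_us >= row.end_us)).any()
            assert contained

    def test_photons_in_at_most_one_burst(self):
        s = self._sim_stream(22)
        out = burst_search(s)
        iv = out.df[["start_us", "end_us"]].to_numpy()
        assert (iv[1:, 0] > iv[:-1, 1]).all()

    def test_es_invariant_under_time_translation(self):
        s = self._sim_stream(23)
        shifted = s.shifted(4 * 50 * 1000)  # whole alternation cycles
        a = burst_search(s)
        b = burst_search(shifted)
        np.testing.assert_allclose(a.df["E_star"], b.df["E_star"])
        np.testing.assert_allclose(a.df["S"], b.df["S"])


class TestThreshold:
    def _set_with_totals(self, totals):
        n = len(totals)
        return BurstSet.from_counts(
            np.arange(n) * 1000, np.arange(n) * 1000 + 500,
            np.asarray(totals), np.zeros(n, int), np.zeros(n, int),
            np.zeros(n, int))

    def test_strict_inequality_at_threshold(self):
        bs = self._set_with_totals([250])
        assert len(threshold_bursts(bs, 250)) == 0

    def test_zero_threshold_is_identity(self):
        bs = self._set_with_totals([1, 5, 10])
        assert len(threshold_bursts(bs, 0)) == 3

    def test_mixed_set_counting(self):
        bs = self._set_with_totals([100, 251, 400])
        assert len(threshold_bursts(bs, 250)) == 2


class TestComputeES:
    @pytest.mark.parametrize("counts,expected", [
        ((50, 50, 100), (0.5, 0.5)),
        ((0, 100, 100), (1.0, 0.5)),
        ((60, 40, 0), (0.4, 1.0)),     # donor-only signature
    ])
    def test_reference_values(self, counts, expected):
        e, s = compute_es(*counts)
        assert e == pytest.approx(expected[0])
        assert s == pytest.approx(expected[1])

    def test_undefined_marked_nan(self):
        e, s = compute_es(0, 0, 100)
        assert np.isnan(e) and s == 0.0
        e, s = compute_es(0, 0, 0)
        assert np.isnan(e) and np.isnan(s)


class TestSpeciesSelection:
    def _set(self):
        n_dd = np.array([50, 50, 90, 0])
        n_da = np.array([50, 50, 10, 0])
        n_aa = np.array([100, 0, 0, 100])   # S = 0.5, 1.0, 1.0, 0.0
        return BurstSet.from_counts(np.arange(4) * 1000,
                                    np.arange(4) * 1000 + 500,
                                    n_dd, n_da, np.zeros(4, int), n_aa)

    def test_full_range_is_identity(self):
        assert len(select_species(self._set(), 0.0, 1.0)) == 4

    def test_donor_only_excluded_by_intermediate_window(self):
        out = select_species(self._set(), 0.3, 0.8)
        assert len(out) == 1
        assert out.df["S"].iloc[0] == pytest.approx(0.5)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            select_species(self._set(), 0.8, 0.3)

    def test_empty_selection_allowed(self):
        out = select_species(self._set(), 0.60, 0.70)
        assert len(out) == 0


class TestESHistogram:
    def _set(self, n=200, seed=3):
        rng = np.random.default_rng(seed)
        n_dd = rng.integers(10, 200, n)
        n_da = rng.integers(10, 200, n)
        n_aa = rng.integers(10, 200, n)
        return BurstSet.from_counts(np.arange(n) * 1000,
                                    np.arange(n) * 1000 + 500,
                                    n_dd, n_da, np.zeros(n, int), n_aa)

    def test_single_burst_single_cell(self):
        bs = BurstSet.from_counts([0], [500], [50], [50], [0], [100])
        h, _, _ = es_histogram(bs)
        assert h.sum() == 1
        assert (h > 0).sum() == 1

    def test_marginal_equals_1d_histogram(self):
        bs = self._set()
        h, ee, _ = es_histogram(bs)
        marginal = h.sum(axis=1)
        h1, _ = np.histogram(bs.df["E_star"], bins=ee)
        np.testing.assert_array_equal(marginal, h1)

    def test_counts_conserved_under_bin_refinement(self):
        bs = self._set()
        coarse, _, _ = es_histogram(bs, np.linspace(0, 1, 11),
                                    np.linspace(0, 1, 11))
        fine, _, _ = es_histogram(bs, np.linspace(0, 1, 101),
                                  np.linspace(0, 1, 101))
        assert coarse.sum() == fine.sum() == len(bs)

    def test_nonmonotone_edges_rejected(self):
        with pytest.raises(ValueError):
            es_histogram(self._set(), np.array([0.0, 0.5, 0.4, 1.0]))
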