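"""Statistical correctness of the synthetic photon-stream generator."""
import numpy as np
import pytest
from scipy import stats

from alexburst import (SimConfig, SimSpecies, inject_aggregates,
                       simulate_burst_table, simulate_dissociation_timecourse,
                       simulate_measurement, simulate_photon_stream,
                       simulate_titration)
from alexburst.burst_search import burst_search, threshold_bursts
from alexburst.aggregate_filter import flag_high_fret


def _one_species(**kw):
    defaults = dict(name="da", fret_e=0.6)
    defaults.update(kw)
    return SimSpecies(**defaults)


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        sp = [_one_species(fraction=0.7), _one_species(name="b", fraction=0.2)]
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(species=sp, duration_s=1.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(species=[_one_species()], duration_s=0.0)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(species=[_one_species()], duration_s=1.0,
                      alternation_period_us=0)

    def test_donor_only_cannot_emit_under_aex(self):
        with pytest.raises(ValueError):
            SimSpecies("d", fret_e=0.0, stoich_class="donor-only",
                       brightness_aex=10.0)

    def test_acceptor_only_cannot_emit_under_dex(self):
        with pytest.raises(ValueError):
            SimSpecies("a", fret_e=0.0, stoich_class="acceptor-only",
                       brightness_dex=10.0)


class TestPhotonStream:
    def test_zero_background_photons_lie_inside_transits(self):
        cfg = SimConfig(species=[_one_species()], duration_s=5.0,
                        background_rate_donor=0.0,
                        background_rate_acceptor=0.0, seed=1)
        stream, truth = simulate_photon_stream(cfg)
        assert len(stream) > 0
        inside = np.zeros(len(stream), dtype=bool)
        for s, e in zip(truth.burst_start_us, truth.burst_end_us):
            inside |= ((stream.timestamps_us >= s)
                       & (stream.timestamps_us <= e))
        assert inside.all()

    def test_transit_durations_exponential_mean(self):
        # mean duration 1/D; 10,000 transits, tolerance 3 standard errors
        cfg = SimConfig(species=[_one_species(diffusion_rate_D=1.0)],
                        duration_s=1000.0, transit_rate_per_s=10.0, seed=2)
        _, truth = simulate_photon_stream(cfg)
        dur_ms = (truth.burst_end_us - truth.burst_start_us) / 1000.0
        n = len(dur_ms)
        assert n > 5000
        se = 1.0 / np.sqrt(n)
        assert abs(dur_ms.mean() - 1.0) < 3 * se

    def test_transit_durations_ks_vs_exponential(self):
        cfg = SimConfig(species=[_one_species(diffusion_rate_D=0.8)],
                        duration_s=1500.0, transit_rate_per_s=10.0, seed=3)
        _, truth = simulate_photon_stream(cfg)
        dur_ms = (truth.burst_end_us - truth.burst_start_us) / 1000.0
        res = stats.kstest(dur_ms[:10000], "expon", args=(0, 1 / 0.8))
        assert res.pvalue > 0.01

    def test_determinism_bit_for_bit(self):
        cfg = SimConfig(species=[_one_species()], duration_s=2.0, seed=9,
                        aggregate_burst_runs=2)
        s1, t1 = simulate_measurement(cfg)
        s2, t2 = simulate_measurement(cfg)
        np.testing.assert_array_equal(s1.timestamps_us, s2.timestamps_us)
        np.testing.assert_array_equal(s1.channel, s2.channel)
        assert t1.equals(t2)

    def test_timestamps_sorted_and_phase_consistent(self):
        cfg = SimConfig(species=[_one_species()], duration_s=2.0, seed=4)
        stream, _ = simulate_photon_stream(cfg)
        assert (np.diff(stream.timestamps_us) >= 0).all()
        period = 2 * cfg.alternation_period_us
        expected = ((stream.timestamps_us % period)
                    >= cfg.alternation_period_us)
        np.testing.assert_array_equal(stream.excitation.astype(bool),
                                      expected)

    def test_empirical_fret_matches_species(self):
        cfg = SimConfig(species=[_one_species(fret_e=0.35)], duration_s=20.0,
                        background_rate_donor=0.0,
                        background_rate_acceptor=0.0, seed=5)
        stream, _ = simulate_photon_stream(cfg)
        dex = stream.excitation == 0
        e_hat = (stream.channel[dex] == 1).mean()
        assert abs(e_hat - 0.35) < 0.01


class TestAggregates:
    def test_zero_runs_leaves_stream_unchanged(self):
        cfg = SimConfig(species=[_one_species()], duration_s=2.0, seed=6,
                        aggregate_burst_runs=0)
        stream, _ = simulate_photon_stream(cfg)
        out, truth = inject_aggregates(stream, cfg)
        np.testing.assert_array_equal(out.timestamps_us, stream.timestamps_us)
        assert len(truth) == 0

    def test_run_count_bounds(self):
        cfg = SimConfig(species=[_one_species()], duration_s=30.0, seed=7,
                        aggregate_burst_runs=5,
                        aggregate_run_length_range=(6, 12))
        stream, _ = simulate_photon_stream(cfg)
        _, truth = inject_aggregates(stream, cfg)
        assert 30 <= len(truth) <= 60
        assert truth.is_aggregate.all()

    def test_injected_run_yields_consecutive_high_e_bursts(self):
        # low transit rate + clear gaps: an injected run should appear as
        # >= 6 consecutive detected bursts with E* > 0.9
        cfg = SimConfig(species=[_one_species()], duration_s=20.0, seed=8,
                        transit_rate_per_s=2.0, aggregate_burst_runs=1,
                        aggregate_run_length_range=(8, 8))
        stream, truth = simulate_measurement(cfg)
        bursts = threshold_bursts(burst_search(stream), 250)
        x = flag_high_fret(bursts, 0.9)
        # longest run of consecutive high-E bursts
        best = run = 0
        for v in x:
            run = run + 1 if v else 0
            best = max(best, run)
        assert best >= 6


class TestBurstTable:
    def test_mean_e_star_matches_fret(self, single_species_config):
        bursts = simulate_burst_table(single_species_config, 5000)
        e = bursts.df["E_star"].dropna()
        assert abs(e.mean() - 0.6) < 0.01

    def test_zero_bursts_rejected(self, single_species_config):
        with pytest.raises(ValueError):
            simulate_burst_table(single_species_config, 0)

    def test_two_species_duration_tail(self):
        # the duration histogram tail follows the two-exponential mixture
        sp = [SimSpecies("slow", fret_e=0.3, diffusion_rate_D=0.6,
                         fraction=0.5),
              SimSpecies("fast", fret_e=0.6, diffusion_rate_D=1.1,
                         fraction=0.5)]
        cfg = SimConfig(species=sp, duration_s=1.0, seed=12)
        bursts = simulate_burst_table(cfg, 40000)
        dur = bursts.df["duration_ms"].to_numpy()
        # empirical tail probability vs analytic mixture survival
        for t in (2.0, 4.0):
            expected = 0.5 * np.exp(-0.6 * t) + 0.5 * np.exp(-1.1 * t)
            observed = (dur > t).mean()
            se = np.sqrt(expected * (1 - expected) / dur.size)
            assert abs(observed - expected) < 4 * se


class TestBindingSimulators:
    def test_titration_half_saturation(self):
        df = simulate_titration(20e-9, [20e-9], 200000, seed=1)
        assert abs(df.bound_fraction[0] - 0.5) < 0.01

    def test_titration_zero_concentration(self):
        df = simulate_titration(20e-9, [0.0], 1000, seed=1)
        assert df.bound_fraction[0] == 0.0

    def test_titration_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_titration(20e-9, [-1e-9], 100)

    def test_dissociation_koff_zero_flat(self):
        df = simulate_dissociation_timecourse(0.0, [0, 1, 5, 10], 500, seed=1)
        assert (df.bound_fraction == 1.0).all()

    def test_dissociation_half_life(self):
        koff = 0.5
        t_half = np.log(2) / koff
        df = simulate_dissociation_timecourse(koff, [t_half], 200000, seed=2)
        assert abs(df.bound_fraction[0] - 0.5) < 0.01

    def test_dissociation_negative_time_rejected(self):
        with pytest.raises(ValueError):
            simulate_dissociation_timecourse(0.5, [-1.0], 100)
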