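"""Generators: statistical fidelity, reproducibility, fixture truths."""

import numpy as np
import pytest

from snarephys.fixtures import (
    MODEL_CHOICES,
    REFERENCE_VALUES,
    calcium_recipe,
    lifetime_rate_matrix,
    snare_domain_ensemble,
    sucrose_pair_params,
    template_complex_ensemble,
    two_state_equilibrium_force,
)
from snarephys.hmm import detect_rips
from snarephys.landscape import FoldingState, StateEnsemble, equilibrium_force
from snarephys.synth import (
    generate_calcium_series,
    generate_minis,
    generate_sucrose_pair,
    generate_train,
    render_trajectory,
    simulate_ctmc,
    simulate_fec,
    substream,
)
from snarephys.vesicle import SucroseProtocol


class TestSimulateCtmc:
    def test_zero_rates_single_dwell(self):
        states, entries = simulate_ctmc(np.zeros((2, 2)), 1, 10.0, substream(0, "z"))
        assert list(states) == [1]
        assert list(entries) == [0.0]

    def test_exponential_dwell_means(self):
        k12, k21 = 5.0, 10.0
        Q = np.array([[-k12, k12], [k21, -k21]])
        states, entries = simulate_ctmc(Q, 0, 1000.0, substream(1, "dwells"))
        dwell = np.diff(entries)
        inner_states = states[:-1][1:]  # drop the first (not censored here but cheap)
        d0 = dwell[1:][inner_states == 0]
        d1 = dwell[1:][inner_states == 1]
        for d, k in [(d0, k12), (d1, k21)]:
            se = (1 / k) / np.sqrt(len(d))
            assert abs(d.mean() - 1 / k) < 3 * se

    def test_occupancy_matches_closed_form(self):
        k12, k21 = 5.0, 10.0
        Q = np.array([[-k12, k12], [k21, -k21]])
        T = 2000.0
        states, entries = simulate_ctmc(Q, 0, T, substream(2, "occ"))
        dur = np.diff(np.append(entries, T))
        occ0 = dur[states == 0].sum() / T
        p0 = k21 / (k12 + k21)
        se = np.sqrt(p0 * (1 - p0) / (T * (k12 + k21)))
        assert abs(occ0 - p0) < 3 * se

    def test_seeded_reproducibility(self):
        Q = np.array([[-3.0, 3.0], [7.0, -7.0]])
        a = simulate_ctmc(Q, 0, 50.0, substream(3, "repro"))
        b = simulate_ctmc(Q, 0, 50.0, substream(3, "repro"))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_ctmc(np.array([[0.0, -1.0], [1.0, 0.0]]), 0, 1.0, substream(0, "x"))


class TestRenderTrajectory:
    def _ens(self):
        return StateEnsemble(
            states=[FoldingState("f", 10.0, -5.0, 2.0), FoldingState("u", 25.0, 0.0, 2.0)]
        )

    def test_noiseless_levels_exact(self, cfg, th):
        ens = self._ens()
        states = np.array([0, 1, 0])
        entries = np.array([0.0, 0.4, 0.7])
        traj = render_trajectory(
            states, entries, ens, 5.0, cfg, th, duration=1.0, noise_sd=0.0, filter_to=None
        )
        levels = np.unique(traj.extension)
        assert len(levels) == 2
        from snarephys.polymer import tether_extension

        assert levels[0] == pytest.approx(tether_extension(5.0, 10.0, cfg, th))
        assert levels[1] == pytest.approx(tether_extension(5.0, 25.0, cfg, th))

    def test_per_state_sample_mean_within_3se(self, cfg, th):
        ens = self._ens()
        Q = np.array([[-5.0, 5.0], [5.0, -5.0]])
        rng = substream(4, "render")
        states, entries = simulate_ctmc(Q, 0, 20.0, rng)
        traj = render_trajectory(states, entries, ens, 5.0, cfg, th, duration=20.0, rng=rng)
        t = traj.time
        truth = states[np.searchsorted(entries, t, side="right") - 1]
        from snarephys.polymer import tether_extension

        for k, L in enumerate([10.0, 25.0]):
            sel = truth == k
            sd = traj.extension[sel].std()
            se = sd / np.sqrt(sel.sum())
            assert abs(traj.extension[sel].mean() - tether_extension(5.0, L, cfg, th)) < 3 * se

    def test_bit_reproducible(self, cfg, th):
        ens = self._ens()
        out = []
        for _ in range(2):
            rng = substream(9, "bits")
            Q = np.array([[-5.0, 5.0], [5.0, -5.0]])
            states, entries = simulate_ctmc(Q, 0, 2.0, rng)
            traj = render_trajectory(states, entries, ens, 5.0, cfg, th, duration=2.0, rng=rng)
            out.append(traj.extension)
        np.testing.assert_array_equal(out[0], out[1])

    def test_default_acquisition_chain_is_20_to_10_khz(self, cfg, th):
        ens = self._ens()
        traj = render_trajectory(
            np.array([0]), np.array([0.0]), ens, 5.0, cfg, th, duration=1.0, seed=0
        )
        assert traj.sample_rate == 10_000.0
        assert traj.metadata["mean_filtered_from_Hz"] == 20_000.0


class TestSimulateFec:
    def test_single_state_smooth_no_rips(self, cfg, th):
        ens = StateEnsemble(states=[FoldingState("only", 15.0, 0.0, 2.0)])
        fec = simulate_fec(ens, cfg, th, (2.0, 15.0), noise_sd=0.2, seed=0)
        assert np.all(np.diff(fec.force) >= 0)
        assert detect_rips(fec) == []

    def test_mean_rip_force_near_equilibrium(self, cfg, th):
        # two-state, 21 pN nm unfolding energy over a 5.4 nm step: unfolding
        # forces concentrate near the equilibrium force (~3.9 pN) when the
        # hopping is fast compared with the pull
        dG = 21.0 / th.kBT
        from snarephys.polymer import contour_for_step

        dl = contour_for_step(5.4, 3.9, cfg, th)
        folded = FoldingState("f", 10.0, -dG, 2.0)
        unfolded = FoldingState("u", 10.0 + dl, 0.0, 2.0)
        ens = StateEnsemble(
            states=[folded, unfolded],
            barriers={
                (0, 1): FoldingState("ts", 10.0 + dl / 2, 3.0, 2.0)
            },
            rate_prefactor=2.0e3,
        )
        f_est = equilibrium_force(dG, 5.4, th)  # 21 pN nm / 5.4 nm ~ 3.9 pN
        first_rips = []
        for s in range(20):
            fec = simulate_fec(
                ens, cfg, th, (1.5, 8.0), pull_speed=30.0, noise_sd=0.0,
                rng=substream(s, "fec"), initial_state=0,
            )
            rips = detect_rips(fec)
            if rips:
                first_rips.append(rips[0]["force"])
        assert len(first_rips) >= 15
        assert np.mean(first_rips) == pytest.approx(f_est, abs=1.0)

    def test_hysteresis_grows_with_pull_speed(self, cfg, th):
        ens = snare_domain_ensemble("ctd", cfg, th)

        def gap(speed):
            gaps = []
            for s in range(6):
                pull = simulate_fec(
                    ens, cfg, th, (10.0, 19.0), pull_speed=speed, noise_sd=0.0,
                    rng=substream(s, f"hyst-{speed}"), initial_state=0,
                )
                relax = simulate_fec(
                    ens, cfg, th, (19.0, 10.0), pull_speed=speed, noise_sd=0.0,
                    rng=substream(s, f"hyst-r-{speed}"), initial_state=1,
                )
                up = detect_rips(pull)
                down = detect_rips(relax)
                if up and down:
                    gaps.append(up[0]["force"] - down[0]["force"])
            return np.mean(gaps) if gaps else 0.0

        assert gap(2000.0) > gap(50.0)


class TestGenerateTrain:
    def test_full_release_no_refill_single_amplitude(self):
        train = generate_train(0.5, 1.0, refill_rate=0.0, n_stim=5, freq=10.0)
        assert train.charges[0] == pytest.approx(0.5)
        np.testing.assert_allclose(train.charges[1:], 0.0, atol=1e-15)

    def test_steady_state_amplitude_closed_form(self):
        # linear refill: steady-state released charge = refill per interval
        train = generate_train(0.5, 0.4, refill_rate=0.08, n_stim=200, freq=40.0)
        assert train.charges[-1] == pytest.approx(0.08 / 40.0, rel=0.01)

    def test_ppr_closed_form_with_refill(self):
        p, refill, freq, pool0 = 0.3, 0.05, 10.0, 0.5
        train = generate_train(pool0, p, refill, n_stim=2, freq=freq)
        expected = (pool0 * (1 - p) + refill / freq) / pool0
        assert train.amplitudes[1] / train.amplitudes[0] == pytest.approx(expected)


class TestSucrosePairAndMinis:
    def test_pair_peak_ordering_and_reproducibility(self):
        control, test = sucrose_pair_params(250)
        protocol = SucroseProtocol(concentration_mM=250)
        a = generate_sucrose_pair(control, test, protocol, rng=substream(5, "pair"))
        b = generate_sucrose_pair(control, test, protocol, rng=substream(5, "pair"))
        assert a["test_clean"].max() > a["control_clean"].max()
        np.testing.assert_array_equal(a["control"], b["control"])

    def test_minis_zero_rate_pure_noise(self):
        t, trace = generate_minis(0.0, 5.0, rng=substream(6, "mini0"))
        assert abs(trace.mean()) < 3 * trace.std() / np.sqrt(len(trace))

    def test_minis_empirical_rate(self):
        rate = 4.0
        t, trace = generate_minis(rate, 60.0, noise_sd=0.002, rng=substream(7, "minirate"))
        from snarephys.ephys import detect_minis

        stats = detect_minis(trace, 10_000.0)
        se = np.sqrt(rate / 60.0)
        assert abs(stats.frequency - rate) < 3 * se

    def test_calcium_series_half_response_near_kd(self):
        recipe = calcium_recipe("test")
        df = generate_calcium_series(
            recipe.kd, recipe.hill_n, concentrations=(recipe.kd,), noise_sd=0.0
        )
        # normalized to the 2 mM flank: response(Kd) = half of the saturating level
        norm = 2.0**recipe.hill_n / (recipe.kd**recipe.hill_n + 2.0**recipe.hill_n)
        assert df["response_true"].iloc[0] == pytest.approx(0.5 / norm)


class TestSimulationRecipe:
    def test_json_round_trip_and_stream(self):
        from snarephys.synth import SimulationRecipe

        r = SimulationRecipe(seed=3, scenario="sucrose-250", truth={"k2_max": 0.35}, noise={"snr": 20})
        r2 = SimulationRecipe.from_json(r.to_json())
        assert r2 == r
        assert r2.rng().random() == r.rng().random()


class TestFixtureTruths:
    """The generator truths are exactly the frozen measured values."""

    def test_reference_values_frozen(self):
        expected = {
            "template_unfolding_energy_kT": 5.1,
            "tomosyn_bound_unfolding_energy_kT": 3.1,
            "open_syntaxin_unfolding_energy_kT": 2.6,
            "ctd_unfolding_energy_kT": 23.0,
            "ntd_unfolding_energy_kT": 35.0,
            "ntd_ctd_rate_separation_fold": 400.0,
            "template_step_nm": 5.4,
            "tomosyn_bound_offset_nm": 1.5,
            "lifetime_open_syntaxin_s": 0.014,
            "lifetime_template_s": 1.6,
            "lifetime_tomosyn_bound_s": 0.7,
            "barrier_shift_250mM_RT": -1.11,
            "barrier_shift_500mM_RT": -0.77,
            "calcium_kd_test_mM": 1.3,
            "calcium_kd_control_mM": 1.7,
        }
        for key, value in expected.items():
            assert REFERENCE_VALUES[key]["value"] == value
            assert REFERENCE_VALUES[key]["note"]  # provenance note present

    def test_template_ensemble_encodes_truths(self, cfg, th):
        ens = template_complex_ensemble(cfg, th)
        assert ens.states[0].zero_force_energy == -5.1
        assert ens.states[1].zero_force_energy == -3.1
        assert ens.states[2].zero_force_energy == 0.0
        # steps reproduce the reported values at the reference force
        from snarephys.polymer import tether_extension

        F = MODEL_CHOICES["template_step_reference_force_pN"]
        x = [
            tether_extension(F, s.unfolded_contour, cfg, th, core_offset=s.core_offset)
            for s in ens.states
        ]
        assert x[2] - x[0] == pytest.approx(5.4, abs=1e-6)
        assert x[1] - x[0] == pytest.approx(1.5, abs=1e-6)

    def test_lifetime_matrix_exit_rates(self):
        Q = lifetime_rate_matrix()
        assert -Q[0, 0] == pytest.approx(1 / 1.6)
        assert -Q[1, 1] == pytest.approx(1 / 0.7)
        assert -Q[2, 2] == pytest.approx(1 / 0.014)

    def test_sucrose_pair_ratio(self):
        for conc, shift in [(250, 1.11), (500, 0.77)]:
            control, test = sucrose_pair_params(conc)
            assert np.log(test.k2_max / control.k2_max) == pytest.approx(shift)
            assert test.rrp_rest == pytest.approx(control.rrp_rest)  # RRP unchanged
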