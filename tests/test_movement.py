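"""The switching state-space model: grid, sampler bookkeeping, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from arstrack import (
    McmcPlan,
    ModelSpec,
    SimConfig,
    build_regular_grid,
    diagnose,
    fit_hssm,
    prob_ars,
    simulate_tracks,
)
from arstrack.argos_io import segment_all, segment_track
from arstrack.movement import gelman_rubin
from arstrack.simulate import ArgosErrorModel
from conftest import make_obs

from test_simulate import tiny_error_model


class TestRegularGrid:
    def test_fix_on_grid_time_has_zero_weight(self):
        seg = segment_track(make_obs(np.arange(25) * 3.0), min_obs=5)[0]
        grid = build_regular_grid(seg, dt=3.0)
        assert np.all(grid.j_weight == 0.0)
        np.testing.assert_array_equal(grid.obs_state, np.arange(25))

    def test_midpoint_fix_has_half_weight(self):
        times = [0.0, 1.5, 3.0, 6.0, 9.0, 12.0]
        seg = segment_track(make_obs(times), min_obs=2)[0]
        grid = build_regular_grid(seg, dt=3.0)
        assert grid.j_weight[1] == pytest.approx(0.5)
        assert grid.obs_state[1] == 0

    def test_state_count_for_180h_span(self):
        # 180 h span at dt=3: floor(span/dt)+1 = 61 states
        seg = segment_track(make_obs(np.linspace(0, 180, 40)), min_obs=5)[0]
        grid = build_regular_grid(seg, dt=3.0)
        assert grid.n_states == 61

    def test_too_short_segment_rejected(self):
        seg = segment_track(make_obs([0.0, 1.0, 2.0, 4.0]), min_obs=2)[0]
        with pytest.raises(ValueError):
            build_regular_grid(seg, dt=3.0)


class TestProbArs:
    @pytest.mark.parametrize("mean_b,expected", [(2.0, 1.0), (1.0, 0.0), (1.5, 0.5)])
    def test_examples(self, mean_b, expected):
        assert prob_ars(mean_b) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            prob_ars(np.array([0.5, 1.2]))


class TestDiagnose:
    def test_identical_chains_shrink_factor_exactly_one(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=500)
        rep = diagnose({"theta": np.stack([c, c])})
        assert rep.table.loc[0, "shrink_factor"] == 1.0

    def test_disjoint_modes_shrink_factor_large(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 1000)
        b = rng.normal(50.0, 1.0, 1000)
        r = gelman_rubin(np.stack([a, b]))
        assert r > 10.0

    def test_white_noise_acf_near_zero(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 2000))
        rep = diagnose({"theta": chains})
        assert abs(rep.table.loc[0, "acf_lag1"]) < 3.0 / np.sqrt(2000)

    def test_single_chain_reported_undefined(self):
        rep = diagnose({"theta": np.random.default_rng(3).normal(size=(1, 200))})
        assert np.isnan(rep.table.loc[0, "shrink_factor"])
        assert any("single chain" in n for n in rep.notes)

    def test_nonconvergent_chains_flagged(self):
        rng = np.random.default_rng(4)
        chains = np.stack([rng.normal(0, 1, 300), rng.normal(5, 1, 300)])
        rep = diagnose({"theta": chains})
        assert not rep.converged and rep.notes


class TestRetainedDraws:
    @pytest.mark.parametrize(
        "chains,post,thin,expected",
        [(2, 30_000, 30, 2000), (2, 3000, 3, 2000), (3, 1000, 7, 3 * 142)],
    )
    def test_plan_identity(self, chains, post, thin, expected):
        plan = McmcPlan(n_chains=chains, burn_in=10, post_burn_in=post, thin=thin)
        assert plan.retained == expected

    def test_fit_returns_planned_draws_and_ordering(self, small_segments):
        plan = McmcPlan(n_chains=2, burn_in=100, post_burn_in=100, thin=5, seed=3)
        series, draws, report = fit_hssm(small_segments, ModelSpec(), plan)
        assert draws.n_draws == plan.retained == 40
        # label switching is excluded by the ordering constraint
        assert (draws.gamma[:, 0] > draws.gamma[:, 1]).all()
        assert set(np.unique(draws.chain)) == {0, 1}
        for s in series:
            assert ((s.data.mean_b >= 1) & (s.data.mean_b <= 2)).all()
            np.testing.assert_allclose(s.data.p_ars, s.data.mean_b - 1)
            np.testing.assert_array_equal(
                s.data.mode_state, np.where(s.data.mean_b > 1.5, 2, 1)
            )

    def test_fit_reproducible_under_seed(self, small_segments):
        plan = McmcPlan(n_chains=2, burn_in=60, post_burn_in=60, thin=3, seed=11)
        _, d1, _ = fit_hssm(small_segments[:1], ModelSpec(), plan)
        _, d2, _ = fit_hssm(small_segments[:1], ModelSpec(), plan)
        np.testing.assert_array_equal(d1.gamma, d2.gamma)
        np.testing.assert_array_equal(d1.x[0], d2.x[0])
        np.testing.assert_array_equal(d1.b[0], d2.b[0])


class TestRecovery:
    def test_noise_free_single_state_path_recovered(self):
        # near-zero measurement noise, single behavioural state: the
        # posterior mean path must match truth within the process scale
        cfg = SimConfig(
            n_whales=1,
            n_steps=120,
            seed=21,
            switch_prob=np.eye(2),
            initial_state=1,
            error_model=tiny_error_model(),
        )
        obs, truth = simulate_tracks(cfg)
        segs = segment_all(obs)
        spec = ModelSpec(error_model=tiny_error_model())
        plan = McmcPlan(n_chains=2, burn_in=200, post_burn_in=300, thin=3, seed=22)
        series, draws, _ = fit_hssm(segs, spec, plan)
        s = series[0]
        tag = s.tag_id
        h = ((s.data.timestamp - truth.tracks[tag]["t0"]) / pd.Timedelta(hours=1)).to_numpy()
        pos = truth.positions_at(tag, h)
        rmse = np.sqrt(
            np.mean(
                (s.data.lon.to_numpy() - pos[:, 0]) ** 2
                + (s.data.lat.to_numpy() - pos[:, 1]) ** 2
            )
        )
        step_scale = np.sqrt(np.trace(cfg.Sigma))
        assert rmse < step_scale

    def test_state_decoding_beats_chance_and_degrades_gracefully(self):
        # matched seeds: well-separated persistence decodes better than
        # barely-separated persistence
        accs = {}
        for gammas in ((0.8, 0.2), (0.55, 0.45)):
            cfg = SimConfig(
                n_whales=1,
                n_steps=300,
                seed=31,
                gamma_transit=gammas[0],
                gamma_ars=gammas[1],
                switch_prob=np.array([[0.97, 0.03], [0.03, 0.97]]),
            )
            obs, truth = simulate_tracks(cfg)
            segs = segment_all(obs)
            plan = McmcPlan(n_chains=2, burn_in=400, post_burn_in=600, thin=3, seed=32)
            series, _, _ = fit_hssm(segs, ModelSpec(), plan)
            n = hit = 0
            for s in series:
                h = (
                    (s.data.timestamp - truth.tracks[s.tag_id]["t0"])
                    / pd.Timedelta(hours=1)
                ).to_numpy()
                bt = truth.states_at(s.tag_id, h)
                hit += (s.data.mode_state.to_numpy() == bt).sum()
                n += len(bt)
            accs[gammas] = hit / n
        assert accs[(0.8, 0.2)] > accs[(0.55, 0.45)]
        assert accs[(0.8, 0.2)] > 0.6

    def test_empty_segments_rejected(self):
        with pytest.raises(ValueError):
            fit_hssm([], ModelSpec(), McmcPlan(burn_in=1, post_burn_in=1, thin=1))
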