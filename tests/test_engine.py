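"""Engine: Wright-Fisher update, migration, burn-in, full scenarios.

The expensive ensemble fixtures (ten replicate reduced-scale GBR warming runs
and their migration-free counterparts) come from conftest and are shared with
the acceptance tests.
"""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import reefadapt as ra
from reefadapt.engine import MetapopState, StagePlan, step_generation
from reefadapt.selection import DemographicState

from conftest import scaled_gbr, tiny_scenario


def _single_locus_state(freq: float, N: int, rng) -> ra.HaplotypeState:
    """Biallelic single-locus population: allelic value 1 = derived allele."""
    v = (rng.random((N, 2, 1)) < freq).astype(float)
    return ra.HaplotypeState(v)


def _closed_step(state: ra.HaplotypeState, N_next: int, rng, mut=0.0) -> ra.HaplotypeState:
    ms = MetapopState(
        states=[state],
        demo=DemographicState(base_sizes=np.array([state.n_individuals])),
        generation=0,
        rng=rng,
    )
    w = [np.ones(state.n_individuals)]
    step_generation(ms, w, np.array([N_next]), np.zeros((1, 1)), mut, 0.2)
    return ms.states[0]


class TestStepGeneration:
    def test_census_conservation(self):
        """One population, no mutation, no noise: census equals the configured
        size every generation (within each burn-in stage)."""
        cfg = tiny_scenario(census=120, mut_rate=0.0)
        res = ra.run_scenario(cfg)
        df = res.trace.df
        assert set(df[df.generation < 100].census) == {12}
        assert set(df[df.generation >= 100].census) == {120}

    def test_neutral_drift_matches_binomial_oracle(self):
        """Allele-frequency change over 10 neutral generations matches an
        independent binomial-resampling chain (KS test over 200 replicates)."""
        N, G, reps, p0 = 50, 10, 200, 0.3
        rng = np.random.default_rng(11)
        engine_freqs = []
        for _ in range(reps):
            st = ra.HaplotypeState((rng.random((N, 2, 1)) < p0).astype(float))
            for _g in range(G):
                st = _closed_step(st, N, rng)
            engine_freqs.append(st.values.mean())
        oracle_rng = np.random.default_rng(12)
        oracle_freqs = []
        for _ in range(reps):
            count = oracle_rng.binomial(2 * N, p0)
            for _g in range(G):
                count = oracle_rng.binomial(2 * N, count / (2 * N))
            oracle_freqs.append(count / (2 * N))
        ks = stats.ks_2samp(engine_freqs, oracle_freqs)
        assert ks.pvalue > 0.001

    def test_realized_migration_fraction(self):
        """With rates[i][j] = 0.005 the realized immigrant fraction over 1e4
        offspring sits inside the binomial 99% interval."""
        m, N = 0.005, 10_000
        rng = np.random.default_rng(13)
        # source monomorphic for allelic value 1 at a single locus; residents 0;
        # an offspring is an immigrant iff both its gametes come from the source
        src = ra.HaplotypeState(np.ones((1000, 2, 1)))
        dst = ra.HaplotypeState.founders(N, 1)
        ms = MetapopState(
            states=[src, dst],
            demo=DemographicState(base_sizes=np.array([1000, N])),
            generation=0,
            rng=rng,
        )
        rates = np.array([[0.0, m], [0.0, 0.0]])
        w = [np.ones(1000), np.ones(N)]
        step_generation(ms, w, np.array([1000, N]), rates, 0.0, 0.2)
        bv = ra.breeding_values(ms.states[1])
        n_immigrants = int(np.sum(bv == 2.0))
        lo, hi = stats.binom.interval(0.99, N, m)
        assert lo <= n_immigrants <= hi

    def test_stage_transition_resizes_through_wf_draw(self):
        cfg = tiny_scenario(census=200)  # stages: (10,10,100), (1,1,200)
        res = ra.run_burnin(cfg)
        df = res.trace.df
        assert set(df[df.generation < 100].census) == {20}
        assert set(df[df.generation >= 100].census) == {200}


class TestStagePlan:
    def test_default_stage_plan(self):
        plan = StagePlan.from_config(ra.load_packaged("gbr"))
        assert plan.stages == ((100, 100, 5000), (10, 10, 5000), (1, 1, 10000))
        assert plan.at(0) == (100, 100)
        assert plan.at(5000) == (10, 10)
        assert plan.at(10_000) == (1, 1)
        assert plan.at(25_000) == (1, 1)  # past burn-in: final stage applies


class TestRunBurnin:
    def test_no_mutation_means_no_variance(self):
        cfg = tiny_scenario(mut_rate=0.0)
        res = ra.run_burnin(cfg)
        assert res.trace.df.genetic_sd.iloc[-1] == 0.0

    def test_staged_burnin_equivalent_to_full_length(self):
        """The rescaled staged burn-in reaches the same equilibrium genetic
        variance (within 2-fold) as a full-length single-stage burn-in."""
        reps = 20
        staged_v, full_v = [], []
        for s in range(reps):
            cfg = tiny_scenario(seed=s, census=200)
            env_staged = dataclasses.replace(
                cfg.environment,
                burnin_stages=(ra.BurninStage(10, 10, 300), ra.BurninStage(1, 1, 600)),
            )
            env_full = dataclasses.replace(
                cfg.environment, burnin_stages=(ra.BurninStage(1, 1, 3000),)
            )
            r1 = ra.run_burnin(dataclasses.replace(cfg, environment=env_staged).validate())
            r2 = ra.run_burnin(
                dataclasses.replace(cfg, seed=1000 + s, environment=env_full).validate()
            )
            staged_v.append(r1.trace.df.genetic_sd.iloc[-1] ** 2)
            full_v.append(r2.trace.df.genetic_sd.iloc[-1] ** 2)
        ratio = np.mean(staged_v) / np.mean(full_v)
        assert 0.5 <= ratio <= 2.0

    def test_pre_warming_variation_is_stable(self, warming_runs):
        """Total metapopulation genetic variation holds steady over the 500
        generations preceding warming: the fitted linear drift over the window
        is a small fraction of the mean level."""
        r = warming_runs[0]
        onset = r.warming_onset
        m = r.meta.df
        sub = m[(m.generation >= onset - 500) & (m.generation < onset)]
        slope = np.polyfit(sub.generation, sub.pooled_sd, 1)[0]
        rel_drift = abs(slope) * 500 / sub.pooled_sd.mean()
        assert rel_drift < 0.15


class TestRunScenario:
    def test_determinism(self):
        cfg = scaled_gbr(17)
        cfg_small = dataclasses.replace(
            cfg,
            environment=dataclasses.replace(
                cfg.environment,
                burnin_stages=(ra.BurninStage(10, 10, 60), ra.BurninStage(1, 1, 120)),
                demography_lead=30,
                warming_generations=30,
            ),
        ).validate()
        a = ra.run_scenario(cfg_small)
        b = ra.run_scenario(cfg_small)
        assert a.trace.to_tsv() == b.trace.to_tsv()
        assert a.meta.to_tsv() == b.meta.to_tsv()
        np.testing.assert_array_equal(a.env.temps, b.env.temps)

    def test_stationary_environment_no_extinction(self):
        cfg = tiny_scenario(census=100)
        env = dataclasses.replace(
            cfg.environment, warming_rate=0.0, warming_generations=700, anomaly_sd=0.25
        )
        cfg = dataclasses.replace(cfg, environment=env).validate()
        res = ra.run_scenario(cfg)
        assert res.metapop_extinction is None
        assert all(g is None for g in res.extinction_generation.values())

    def test_metapopulation_persists_through_warming(self, warming_runs):
        """The pre-adapted metapopulation survives at least 20 warming
        generations in (nearly) every replicate."""
        survived = [r.warming_generations_survived for r in warming_runs]
        assert sum(s >= 20 for s in survived) >= 8

    def test_warm_adapted_populations_go_extinct_first(self, warming_runs):
        """The initially warm-adapted populations (W, M) collapse before the
        mild- and cool-adapted ones under warming."""
        ok = 0
        for r in warming_runs:
            e = {
                k: (v if v is not None else np.inf)
                for k, v in r.extinction_generation.items()
            }
            if max(e["W"], e["M"]) <= min(e["S"], e["O"], e["K"]):
                ok += 1
        assert ok >= 8

    def test_local_adaptation_under_efficient_selection(self, narrow_burnin):
        """With perfect heritability and narrow tolerance each population's
        mean breeding value settles within 0.25 °C of its own thermal offset."""
        df = narrow_burnin.trace.df
        end = df[df.generation >= df.generation.max() - 100]
        cfg = narrow_burnin.config
        for name, offset in zip(cfg.names, cfg.offsets):
            bv = end[end.population == name].mean_breeding.mean()
            assert bv == pytest.approx(offset, abs=0.25), name

    def test_migration_contributes_to_persistence(self, warming_runs, nomig_runs):
        """Median survival with the reference migration matrix is at least that
        with migration zeroed (paired seeds)."""
        with_m = np.median([r.warming_generations_survived for r in warming_runs])
        without = np.median([r.warming_generations_survived for r in nomig_runs])
        assert with_m >= without

    def test_populations_exchangeable_without_migration(self):
        """With migration off and identical offsets, per-population end-state
        genetic SDs are similar across populations (no hidden coupling)."""
        cfg = tiny_scenario(n_pops=3, census=150, migration=0.0, mut_rate=5e-4)
        res = ra.run_burnin(cfg)
        df = res.trace.df
        end = df[df.generation >= df.generation.max() - 50]
        sds = end.groupby("population").genetic_sd.mean()
        assert sds.max() / sds.min() < 5  # same distribution, independent draws


class TestMutationRateRegimes:
    def test_low_mu_initial_response_high_mu_sustained(self, mu_sweep_runs):
        """A ten-fold lower mutation rate still allows the initial adaptive
        response (genetic rescue from standing variation) but not sustained
        adaptation; a ten-fold higher rate lets the metapopulation ride out
        the whole warming period."""
        for seed in (0, 1):
            low = mu_sweep_runs[(seed, 1e-6)]
            high = mu_sweep_runs[(seed, 1e-4)]
            horizon = low.config.environment.warming_generations
            # initial response: the cool population's mean breeding value rises
            # during early warming even at low mutation rate
            df = low.trace.df
            k = df[df.population == "K"]
            onset = low.warming_onset
            pre = k[(k.generation >= onset - 100) & (k.generation < onset)].mean_breeding.mean()
            early = k[(k.generation >= onset + 40) & (k.generation < onset + 50)].mean_breeding.mean()
            assert early > pre
            # no sustained adaptation at low mu; indefinite adaptation at high mu
            assert low.warming_generations_survived < horizon
            assert high.warming_generations_survived == horizon
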