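"""Population-simulator tests: growth, bottlenecks, mutation supply, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from degensim.popsim import (
    DEFAULT_SPECTRUM,
    ConfigError,
    ExtinctionError,
    GenotypeClass,
    PopulationState,
    RegimeConfig,
    apply_dilution,
    apply_heat_shock,
    grow_transfer,
    null_spo0a_class,
    sample_isolates,
    simulate_series,
    spawn_mutations,
    wt_class,
)
from degensim.mutstats import classify_substitution


def make_state(veg, spores=None, subculture=0):
    return PopulationState(
        subculture_index=subculture,
        vegetative=dict(veg),
        spores=dict(spores or {k: 0 for k in veg}),
    )


class TestGrowTransfer:
    def test_sporulation_gives_one_log_vegetative_drop(self, rng):
        """A 90%-sporulating WT culture grown to 1e9 retains ~1e8 vegetative cells."""
        regime = RegimeConfig(carrying_capacity=10**9)
        state = make_state({"WT": 10**8})
        out = grow_transfer(state, [wt_class()], regime, rng)
        assert 0.9e8 < out.vegetative["WT"] < 1.1e8
        assert 0.85e9 < out.spores["WT"] < 0.95e9
        assert out.culture_age_h == 24.0

    def test_neutral_growth_preserves_expected_frequencies(self, rng):
        """Equal fitness, no frequency dependence: drift only, mean frequency constant."""
        a = GenotypeClass("a", sporulation_fraction=0.0)
        b = GenotypeClass("b", sporulation_fraction=0.0)
        regime = RegimeConfig(carrying_capacity=1000)
        freqs = []
        for _ in range(400):
            out = grow_transfer(make_state({"a": 50, "b": 50}), [a, b], regime, rng)
            freqs.append(out.vegetative["a"] / out.total_vegetative)
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 0.5) < 3 * se

    def test_selection_matches_logistic_recursion_oracle(self, rng):
        """Fitness 1.2 vs 1.0 over 10 generations follows x' = 1.2x/(1.2x + 1 - x)."""
        x = 0.5
        for _ in range(10):
            x = 1.2 * x / (1.2 * x + (1 - x))
        mut = GenotypeClass("mut", baseline_fitness=1.2)
        wt = GenotypeClass("wt")
        regime = RegimeConfig(carrying_capacity=1_024_000)
        freqs = []
        for _ in range(1000):
            out = grow_transfer(make_state({"mut": 500, "wt": 500}), [mut, wt], regime, rng)
            freqs.append(out.vegetative["mut"] / out.total_vegetative)
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - x) < 3 * se

    def test_phenotypes_are_frequency_weighted_yields(self, rng):
        """A pure null-Spo0A culture emits zero solvents (degenerate semantics)."""
        null = null_spo0a_class("FW")
        assert null.solvent_yield == 0.0 and null.sporulation_fraction == 0.0
        regime = RegimeConfig(carrying_capacity=10_000)
        out = grow_transfer(make_state({"FW": 1000}), [null], regime, rng)
        assert out.solvents_gL == 0.0
        assert out.acids_gL > 0

    def test_post24h_decay_only_beyond_24h(self, rng):
        null = null_spo0a_class("FW")
        reg24 = RegimeConfig(carrying_capacity=10_000, transfer_interval_h=24)
        reg72 = RegimeConfig(carrying_capacity=10_000, transfer_interval_h=72)
        v24 = [
            grow_transfer(make_state({"FW": 1000}), [null], reg24, rng).vegetative["FW"]
            for _ in range(20)
        ]
        v72 = [
            grow_transfer(make_state({"FW": 1000}), [null], reg72, rng).vegetative["FW"]
            for _ in range(20)
        ]
        # survival over 48 extra hours at 0.953/h is ~10%
        assert np.mean(v24) == pytest.approx(10_000, rel=0.05)
        assert np.mean(v72) == pytest.approx(10_000 * 0.953**48, rel=0.25)

    def test_errors(self, rng):
        regime = RegimeConfig(carrying_capacity=1000)
        with pytest.raises(ExtinctionError):
            grow_transfer(make_state({"WT": 0}), [wt_class()], regime, rng)
        with pytest.raises(ConfigError):
            grow_transfer(make_state({"WT": 5000}), [wt_class()], regime, rng)
        with pytest.raises(ConfigError):
            grow_transfer(make_state({"ghost": 10}), [wt_class()], regime, rng)


class TestDilution:
    def test_binomial_expectation(self, rng):
        regime = RegimeConfig(dilution_factor=0.1)
        totals = [
            apply_dilution(make_state({"WT": 10**6}), regime, rng).vegetative["WT"]
            for _ in range(400)
        ]
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - 10**5) < 3 * se

    def test_factor_one_disallowed(self):
        with pytest.raises(ConfigError):
            RegimeConfig(dilution_factor=1.0)

    def test_resets_phenotype_accumulators(self, rng):
        state = make_state({"WT": 1000})
        state.solvents_gL = 5.0
        state.acids_gL = 2.0
        out = apply_dilution(state, RegimeConfig(), rng)
        assert out.solvents_gL == 0.0 and out.acids_gL == 0.0

    def test_unbiased_against_exhaustive_enumeration(self, rng):
        """Joint outcome distribution at N=10 matches the exact product-binomial pmf."""
        regime = RegimeConfig(dilution_factor=0.1)
        n_draws = 20_000
        observed = np.zeros((6, 6))
        for _ in range(n_draws):
            out = apply_dilution(make_state({"a": 5, "b": 5}), regime, rng)
            observed[out.vegetative["a"], out.vegetative["b"]] += 1
        # exact pmf by enumeration over all 36 outcomes
        pmf_one = np.array([stats.binom.pmf(k, 5, 0.1) for k in range(6)])
        expected = np.outer(pmf_one, pmf_one) * n_draws
        mask = expected >= 5
        obs = np.append(observed[mask], observed[~mask].sum())
        exp = np.append(expected[mask], expected[~mask].sum())
        assert stats.chisquare(obs, exp).pvalue > 1e-3


class TestHeatShock:
    def test_definitional_example(self, rng):
        state = make_state({"WT": 10**8, "FW": 10**7}, {"WT": 10**6, "FW": 0})
        out = apply_heat_shock(state, 1.0, rng)
        assert out.vegetative == {"WT": 10**6, "FW": 0}
        assert out.total_spores == 0

    def test_nonsporulator_always_eliminated(self, rng):
        for _ in range(10):
            state = make_state({"WT": 10**6, "FW": 10**6}, {"WT": 10**4, "FW": 0})
            out = apply_heat_shock(state, 0.8, rng)
            assert out.vegetative["FW"] == 0

    def test_binomial_germination_mean(self, rng):
        survivors = [
            apply_heat_shock(make_state({"WT": 0}, {"WT": 10**6}), 0.5, rng).vegetative["WT"]
            for _ in range(400)
        ]
        se = np.std(survivors, ddof=1) / np.sqrt(len(survivors))
        assert abs(np.mean(survivors) - 5e5) < 3 * se

    def test_no_spores_is_extinction(self, rng):
        with pytest.raises(ExtinctionError):
            apply_heat_shock(make_state({"FW": 10**6}), 1.0, rng)


class TestSpawnMutations:
    def test_zero_rate_never_mutates(self, rng):
        regime = RegimeConfig(mutation_rate=0.0)
        state = make_state({"WT": 10_000})
        for _ in range(5):
            state, new_classes, records = spawn_mutations(
                state, [wt_class()], regime, DEFAULT_SPECTRUM, {"other": 1.0}, rng
            )
            assert new_classes == [] and records == []

    def test_zero_weights_rejected(self, rng):
        with pytest.raises(ConfigError):
            spawn_mutations(
                make_state({"WT": 100}),
                [wt_class()],
                RegimeConfig(),
                DEFAULT_SPECTRUM,
                {"other": 0.0},
                rng,
            )

    def test_spectrum_fraction_matches_multinomial_oracle(self, rng):
        """Realized G:C>T:A share over >10k SNPs is within 1% of the 0.87 weight."""
        regime = RegimeConfig(mutation_rate=0.12, carrying_capacity=200_000)
        state = make_state({"WT": 100_000})
        _, _, records = spawn_mutations(
            state, [wt_class()], regime, DEFAULT_SPECTRUM, {"other": 1.0}, rng
        )
        snps = [r for r in records if r.kind == "SNP"]
        assert len(snps) > 10_000
        frac = np.mean([classify_substitution(r.ref, r.alt)[0] == "G:C>T:A" for r in snps])
        assert abs(frac - 0.87) < 0.01

    def test_spo0a_hit_yields_null_class(self, rng):
        regime = RegimeConfig(mutation_rate=0.001)
        state = make_state({"WT": 50_000})
        _, new_classes, records = spawn_mutations(
            state, [wt_class()], regime, DEFAULT_SPECTRUM, {"hotspot2_spo0a": 1.0}, rng
        )
        assert new_classes
        for cls in new_classes:
            assert cls.sporulation_fraction == 0.0
            assert cls.solvent_yield == 0.0
            assert cls.morphotype == "FW"
            assert len(cls.mutations) == 1
        for rec in records:
            assert 1_900_001 <= rec.pos <= 1_901_700

    def test_carrier_hit_inherits_parent_parameters(self, rng):
        regime = RegimeConfig(mutation_rate=0.001)
        parent = null_spo0a_class("FW")
        state = make_state({"FW": 50_000})
        _, new_classes, _ = spawn_mutations(
            state, [parent], regime, DEFAULT_SPECTRUM, {"other": 1.0}, rng
        )
        assert new_classes
        for cls in new_classes:
            assert cls.baseline_fitness == parent.baseline_fitness
            assert cls.morphotype == "FW"
            assert cls.severity == parent.severity


class TestSimulateSeries:
    def test_deterministic_under_fixed_seed(self):
        a = simulate_series(seed=42, regime=RegimeConfig(n_subcultures=4))
        b = simulate_series(seed=42, regime=RegimeConfig(n_subcultures=4))
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(a.mutations, b.mutations)
        pd.testing.assert_frame_equal(a.truth_af, b.truth_af)
        assert a.states[3].vegetative == b.states[3].vegetative

    def test_counts_nonnegative_and_capacity_bounded(self):
        series = simulate_series(seed=3, regime=RegimeConfig(n_subcultures=6))
        for state in series.states:
            assert all(v >= 0 for v in state.vegetative.values())
            assert all(s >= 0 for s in state.spores.values())
            assert state.total_vegetative <= 10_000
        fracs = series.phenotypes[[f"frac_{m}" for m in ("RD", "DCOG", "CIC", "FW")]]
        assert np.allclose(fracs.sum(axis=1), 1.0)

    def test_truth_af_in_unit_interval_and_complete(self):
        series = simulate_series(seed=5, regime=RegimeConfig(n_subcultures=5))
        assert len(series.truth_af) == len(series.mutations)
        vals = series.truth_af.to_numpy()
        assert np.all(vals >= 0) and np.all(vals <= 1)
        # a mutation cannot pre-date its origin subculture
        origin = series.mutations.set_index("mut_id")["subculture"]
        for mut_id, row in series.truth_af.iterrows():
            first = origin[mut_id]
            if first > 0:
                assert row[first - 1] == 0.0

    def test_neutral_series_keeps_frequencies(self):
        """mu = 0 with equal classes: expected composition is flat over transfers."""
        a = GenotypeClass("a", sporulation_fraction=0.0)
        b = GenotypeClass("b", sporulation_fraction=0.0)
        regime = RegimeConfig(n_subcultures=5, mutation_rate=0.0)
        freqs = []
        for seed in range(300):
            s = simulate_series(
                [a, b],
                regime,
                seed=seed,
                initial_counts={"a": 500, "b": 500},
                keep_states=False,
                compute_truth=False,
            )
            last = s.phenotypes.index[-1]
            freqs.append(s.phenotypes.loc[last, "frac_RD"])  # both RD: sanity 1.0
        assert np.allclose(freqs, 1.0)
        freqs = []
        for seed in range(300):
            s = simulate_series(
                [a, b],
                regime,
                seed=seed,
                initial_counts={"a": 500, "b": 500},
            )
            state = s.states[-1]
            freqs.append(state.frequency("a"))
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 0.5) < 3 * se

    def test_nonsporulators_never_hold_spores(self):
        """Null-Spo0A (FW) classes cannot appear in any spore pool, so every
        heat-shock bottleneck removes them from the next inoculum."""
        series = simulate_series(
            seed=9, regime=RegimeConfig(n_subcultures=6, heat_shock=True)
        )
        fw_ids = set(
            series.class_table.loc[
                series.class_table["morphotype"] == "FW", "class_id"
            ]
        )
        for state in series.states:
            for cid, n in state.spores.items():
                if cid in fw_ids:
                    assert n == 0

    def test_sample_isolates_matches_ledger(self, rng):
        series = simulate_series(seed=13, regime=RegimeConfig(n_subcultures=5))
        catalogue = sample_isolates(series, 5, 20, rng)
        counts: dict[str, int] = {}
        for rec in catalogue:
            counts[rec.isolate_id] = counts.get(rec.isolate_id, 0) + 1
        # each isolate's record count must equal the cumulative mutation count
        # of a class alive at the sampled subculture
        state = next(s for s in series.states if s.subculture_index == 5)
        alive = set(state.vegetative) | set(state.spores)
        n_mut_alive = {
            int(row.n_mutations)
            for row in series.class_table.itertuples()
            if row.class_id in alive
        }
        assert set(counts.values()) <= n_mut_alive
        assert len(counts) <= 20
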