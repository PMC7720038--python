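import numpy as np
import pandas as pd
import pytest

from cats_ards.errors import ConfigError
from cats_ards.synthetic import (SimulationConfig, assign_labels,
                                 generate_clinical, generate_cohort,
                                 generate_expression, generate_outcomes,
                                 largest_remainder_counts,
                                 simulate_fine_gray_cohort)


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="subtype_proportions"):
            SimulationConfig(subtype_proportions=(0.5, 0.2, 0.2))

    def test_probability_out_of_range(self):
        with pytest.raises(ConfigError, match="immunocompromised_prev"):
            SimulationConfig(immunocompromised_prev=(0.3, 1.2, 0.1))

    def test_informative_genes_bounded(self):
        with pytest.raises(ConfigError, match="n_informative"):
            SimulationConfig(n_genes=100, n_informative=200)

    def test_vector_length_must_match_k(self):
        with pytest.raises(ConfigError, match="death_prob_28d"):
            SimulationConfig(k_true=2, subtype_proportions=(0.5, 0.5),
                             immunocompromised_prev=(0.2, 0.2),
                             death_prob_28d=(0.2, 0.2, 0.2))


def test_largest_remainder_exact_study_sizes():
    counts = largest_remainder_counts((31 / 96, 29 / 96, 36 / 96), 96)
    np.testing.assert_array_equal(counts, [31, 29, 36])


def test_label_counts_match_proportions():
    config = SimulationConfig()
    labels = assign_labels(config)
    assert labels.value_counts().sort_index().tolist() == [31, 29, 36]


class TestDeterminism:
    def test_same_seed_identical_cohort(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        np.testing.assert_array_equal(a.expression.values,
                                      b.expression.values)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        assert a.events.subject_ids == b.events.subject_ids
        for sid in a.events.subject_ids:
            assert a.events[sid].intervals == b.events[sid].intervals
            assert a.events[sid].death_day == b.events[sid].death_day

    def test_different_seed_differs(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config.with_seed(small_config.seed + 1))
        assert not np.array_equal(a.expression.values, b.expression.values)


class TestExpression:
    def test_informative_blocks_shifted(self, small_config):
        matrix, labels = generate_expression(small_config)
        lab = labels.to_numpy()
        block = small_config.n_informative // small_config.k_true
        vals = matrix.values
        for k in range(1, small_config.k_true + 1):
            rows = slice((k - 1) * block, k * block)
            own = vals[rows][:, lab == k].mean()
            other = vals[rows][:, lab != k].mean()
            assert own - other == pytest.approx(small_config.effect_size,
                                                abs=0.35)

    def test_no_signal_gives_chance_level_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        from cats_ards.cluster import kmeans

        aris = []
        for seed in range(25):
            config = SimulationConfig(n_subjects=48, n_genes=200,
                                      n_informative=60, effect_size=0.0,
                                      subtype_proportions=(1/3, 1/3, 1/3),
                                      seed=seed)
            matrix, labels = generate_expression(config)
            res = kmeans(matrix.subjects_by_genes(), 3, n_init=5, seed=seed)
            aris.append(adjusted_rand_score(labels.to_numpy(), res.labels))
        assert abs(np.mean(aris)) < 0.05

    def test_recovery_improves_with_effect_size(self):
        from sklearn.metrics import adjusted_rand_score

        from cats_ards.cluster import kmeans

        mean_ari = []
        for effect in (0.0, 0.5, 1.0, 2.0):
            aris = []
            for seed in range(12):
                config = SimulationConfig(n_subjects=60, n_genes=400,
                                          n_informative=90,
                                          effect_size=effect,
                                          subtype_proportions=(1/3, 1/3, 1/3),
                                          seed=seed)
                matrix, labels = generate_expression(config)
                res = kmeans(matrix.subjects_by_genes(), 3, n_init=5,
                             seed=seed)
                aris.append(adjusted_rand_score(labels.to_numpy(),
                                                res.labels))
            mean_ari.append(np.mean(aris))
        assert np.all(np.diff(mean_ari) >= -0.02)  # monotone in the mean
        assert mean_ari[-1] > 0.9

    def test_single_population_selects_k1(self):
        from cats_ards.cluster import gap_statistic, select_k

        picks = []
        for seed in range(6):
            config = SimulationConfig(n_subjects=40, n_genes=150,
                                      k_true=1, n_informative=30,
                                      subtype_proportions=(1.0,),
                                      immunocompromised_prev=(0.3,),
                                      death_prob_28d=(0.2,), seed=seed)
            matrix, _ = generate_expression(config)
            curve = gap_statistic(matrix.subjects_by_genes(), k_max=5, B=8,
                                  seed=seed, n_init=3)
            picks.append(select_k(curve, min_cluster_size=5).selected_k)
        assert sum(k == 1 for k in picks) > len(picks) / 2


class TestClinical:
    def test_prevalence_matches_targets_within_3se(self):
        config = SimulationConfig(n_subjects=3000, n_genes=10,
                                  n_informative=9, seed=5)
        labels = assign_labels(config)
        clin = generate_clinical(labels, config)
        lab = labels.to_numpy()
        for k, target in enumerate(config.immunocompromised_prev, start=1):
            flags = clin.loc[lab == k, "immunocompromised"]
            se = np.sqrt(target * (1 - target) / len(flags))
            assert abs(flags.mean() - target) <= 3 * se

    def test_zero_prevalence_zero_flags(self):
        config = SimulationConfig(immunocompromised_prev=(0.0, 0.0, 0.0))
        labels = assign_labels(config)
        clin = generate_clinical(labels, config)
        assert not clin["immunocompromised"].any()
        assert not clin["stem_cell_transplant"].any()

    def test_validates_against_schema(self, small_cohort):
        from cats_ards.dataio import validate_clinical

        validate_clinical(small_cohort.clinical)  # must not raise


class TestOutcomes:
    def test_death_fraction_calibrated_at_large_n(self):
        config = SimulationConfig(n_subjects=5000, n_genes=10,
                                  n_informative=9, seed=9)
        labels = assign_labels(config)
        events = generate_outcomes(labels, config)
        lab = labels.to_numpy()
        ids = np.asarray(labels.index)
        for k, target in enumerate(config.death_prob_28d, start=1):
            sub = ids[lab == k]
            frac = np.mean([not events[s].picu_survivor for s in sub])
            se = np.sqrt(target * (1 - target) / len(sub))
            assert abs(frac - target) <= 3 * se

    def test_no_deaths_when_probability_zero(self):
        config = SimulationConfig(death_prob_28d=(0.0, 0.0, 0.0))
        labels = assign_labels(config)
        events = generate_outcomes(labels, config)
        assert all(rec.picu_survivor for rec in events)

    def test_every_subject_has_exactly_one_terminal_state(self, small_cohort):
        from cats_ards.clinical import first_liberation_time

        for rec in small_cohort.events:
            t, ev = first_liberation_time(rec)
            assert ev in (0, 1, 2)
            assert 0 < t <= 28

    def test_fine_gray_cohort_marginals(self):
        # with beta=0 the event-1 fraction approaches p_base (censoring aside)
        t, ev, _ = simulate_fine_gray_cohort(4000, [0.0], p_base=0.6,
                                             rate=0.3, seed=0)
        frac1 = np.mean(ev == 1)
        assert frac1 == pytest.approx(0.6, abs=0.03)
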