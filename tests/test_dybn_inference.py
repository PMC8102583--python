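"""Tests of panel alignment, the BGe score, structure MCMC and recovery."""

import numpy as np
import pandas as pd
import pytest
from chemoswitch.dybn_inference import (
    BGeHyperparams,
    TransitionDataset,
    align_panel,
    auroc,
    bge_local_score,
    consensus,
    exact_posterior_edges,
    mh_sample_structures,
    recovery_metrics,
    transitions,
)
from chemoswitch.dybn_inference import _log_marginal_subset
from chemoswitch.synthetic_cohort import (
    default_mediator_map,
    generate_cohort,
)
from oracles import numeric_marginal_1d, numeric_marginal_2d

@pytest.fixture(scope="module")
def toy_pair():
    """Lagged pair: B(t+1) = 0.9 A(t) + noise."""
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 200)
    b = 0.9 * a + rng.normal(0, 0.5, 200)
    return TransitionDataset(np.c_[a, b * 0], np.c_[a * 0, b], ("A", "B"))


class TestBGeScore:
    def test_empty_parent_score_matches_numeric_integration(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        data = TransitionDataset(x[:, None] * 0, x[:, None], ("A",))
        hyper = BGeHyperparams(d=1)
        closed = bge_local_score("A", [], data, hyper)
        numeric = numeric_marginal_1d(x, 1, hyper.alpha_mu, hyper.aw, hyper.t)
        assert abs(closed - numeric) <= 1e-4

    def test_single_parent_score_matches_numeric_integration(self):
        rng = np.random.default_rng(3)
        n = 8
        a = rng.normal(0, 1, n)
        b = 0.7 * a + rng.normal(0, 0.8, n)
        data = TransitionDataset(np.c_[a, b * 0], np.c_[a * 0, b], ("A", "B"))
        hyper = BGeHyperparams(d=2)
        closed = bge_local_score("B", ["A"], data, hyper)
        # oracle: joint marginal of the (parent, child) block minus the
        # marginal of the parent block, each integrated numerically
        joint = numeric_marginal_2d(np.c_[a, b], hyper.alpha_mu, hyper.aw, hyper.t)
        marg = numeric_marginal_1d(a, 2, hyper.alpha_mu, hyper.aw, hyper.t)
        assert abs(closed - (joint - marg)) <= 1e-4

    def test_true_parent_beats_empty_set(self, toy_pair):
        hyper = BGeHyperparams(d=2)
        gain = bge_local_score("B", ["A"], toy_pair, hyper) - bge_local_score(
            "B", [], toy_pair, hyper
        )
        assert gain > 0

    def test_duplicating_data_is_not_score_doubling_but_strengthens_evidence(
        self, toy_pair
    ):
        hyper = BGeHyperparams(d=2)

        def gain(data):
            return bge_local_score("B", ["A"], data, hyper) - bge_local_score(
                "B", [], data, hyper
            )

        doubled = TransitionDataset(
            np.vstack([toy_pair.current] * 2),
            np.vstack([toy_pair.following] * 2),
            toy_pair.mediators,
        )
        single = bge_local_score("B", ["A"], toy_pair, hyper)
        double = bge_local_score("B", ["A"], doubled, hyper)
        assert abs(double - 2 * single) > 1.0  # marginals do not simply double
        assert gain(doubled) > gain(toy_pair)

    def test_score_equivalence_on_three_variable_static_embedding(self):
        # Markov-equivalent DAGs must score identically; the v-structure
        # (which is not equivalent) must not
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal(
            [0, 0, 0], [[1, 0.6, 0.3], [0.6, 1, 0.5], [0.3, 0.5, 1]], size=40
        )
        static = TransitionDataset(z, z, ("A", "B", "C"))
        hyper = BGeHyperparams(d=3)

        def total(parent_sets):
            return sum(
                bge_local_score(t, pa, static, hyper)
                for t, pa in parent_sets.items()
            )

        chain = total({"A": [], "B": ["A"], "C": ["B"]})
        reverse = total({"C": [], "B": ["C"], "A": ["B"]})
        fork = total({"B": [], "A": ["B"], "C": ["B"]})
        vstruct = total({"A": [], "C": [], "B": ["A", "C"]})
        assert abs(chain - reverse) <= 1e-8
        assert abs(chain - fork) <= 1e-8
        assert abs(chain - vstruct) > 1e-3

    def test_insufficient_pairs_rejected(self):
        data = TransitionDataset(np.zeros((3, 2)), np.zeros((3, 2)), ("A", "B"))
        with pytest.raises(ValueError, match="n_pairs"):
            bge_local_score("B", ["A"], data, BGeHyperparams(d=2))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError, match="alpha_w"):
            BGeHyperparams(d=3, alpha_w=3.0).validate()
        with pytest.raises(ValueError, match="alpha_mu"):
            BGeHyperparams(d=3, alpha_mu=-1.0).validate()


class TestAlignPanel:
    def test_noise_free_panel_preserves_latent_level_ranks(self, ref_model):
        cohort = generate_cohort(
            0, 0, 4, seed=5, mediator_map=default_mediator_map(sigma=0.0),
            model=ref_model, n_healthy=0,
        )
        panel = align_panel(cohort, mediators=["MCP1", "IL6", "IP10", "MIG", "IFNg"])
        j = panel.mediators.index("MCP1")
        sched_steps = [0, 1, 2, 3, 6, 9, 12, 15, 18, 21]
        for p, rec in enumerate(cohort.records):
            latent = rec.latent.series("MCP1")[sched_steps]
            z = panel.data[p, :, j]
            # the log map is monotone, so z-score order mirrors level order
            for s1 in range(len(latent)):
                for s2 in range(len(latent)):
                    if latent[s1] < latent[s2]:
                        assert z[s1] < z[s2]

    def test_mediator_mean_zero_variance_one(self):
        cohort = generate_cohort(2, 2, 2, seed=8, n_healthy=0)
        panel = align_panel(cohort)
        flat = panel.data.reshape(-1, panel.data.shape[-1])
        assert np.allclose(np.nanmean(flat, axis=0), 0, atol=1e-9)
        assert np.allclose(np.nanstd(flat, axis=0), 1, atol=1e-9)

    def test_constant_mediator_raises_naming_it(self, ref_model):
        cohort = generate_cohort(
            2, 0, 0, seed=1, mediator_map=default_mediator_map(sigma=0.0),
            model=ref_model, n_healthy=0,
        )
        with pytest.raises(ValueError, match="IL8"):
            align_panel(cohort, mediators=["IL8"])

    def test_duplicated_cohort_gives_identical_statistics(self):
        cohort = generate_cohort(2, 2, 2, seed=4, n_healthy=0)
        df = cohort.table
        clone = df.copy()
        clone["patient_id"] = clone["patient_id"] + "-copy"
        both = pd.concat([df, clone], ignore_index=True)
        a = align_panel(df)
        b = align_panel(both)
        assert np.allclose(a.data, b.data[: a.n_patients], equal_nan=True)

    def test_patient_with_single_sample_dropped_with_warning(self, caplog):
        cohort = generate_cohort(2, 0, 0, seed=2, n_healthy=0)
        df = cohort.table
        lone = df[df.patient_id == df.patient_id.iloc[0]]
        lone = lone[lone.time_h == 0.0].copy()
        lone["patient_id"] = "mild-lonely"
        import logging

        with caplog.at_level(logging.WARNING):
            panel = align_panel(pd.concat([df, lone], ignore_index=True))
        assert "mild-lonely" not in panel.patients
        assert "dropping" in caplog.text

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            align_panel(pd.DataFrame(columns=["patient_id", "group", "time_h",
                                              "mediator", "value_pg_ml"]))

    def test_transitions_never_span_patients(self):
        cohort = generate_cohort(2, 2, 2, seed=3, n_healthy=0)
        panel = align_panel(cohort)
        data = transitions(panel)
        n_slots = panel.data.shape[1]
        assert data.n_pairs == panel.n_patients * (n_slots - 1)


class TestSampler:
    def test_posterior_prefers_true_edge_direction(self, toy_pair):
        rng_data = toy_pair
        post = mh_sample_structures(rng_data, fan_in=1, iters=6000, seed=7)
        assert post.freq("A", "B") > post.freq("B", "A")

    def test_boundary_single_sample_iteration(self, toy_pair):
        post = mh_sample_structures(toy_pair, fan_in=1, iters=5, burn_in=4, seed=0)
        assert set(np.unique(post.frequency)) <= {0.0, 1.0}

    def test_same_seed_reproduces_frequencies(self, toy_pair):
        a = mh_sample_structures(toy_pair, iters=3000, seed=5)
        b = mh_sample_structures(toy_pair, iters=3000, seed=5)
        assert np.array_equal(a.frequency, b.frequency)

    def test_invalid_fan_in_and_burn_in_rejected(self, toy_pair):
        with pytest.raises(ValueError, match="fan_in"):
            mh_sample_structures(toy_pair, fan_in=0, iters=10)
        with pytest.raises(ValueError, match="burn_in"):
            mh_sample_structures(toy_pair, iters=10, burn_in=10)

    def test_mcmc_approaches_exact_enumeration_posterior(self, toy_pair):
        exact = exact_posterior_edges(toy_pair, fan_in=2)
        post = mh_sample_structures(toy_pair, fan_in=2, iters=20000, seed=1)
        assert np.abs(post.frequency - exact.frequency).max() <= 0.07


class TestConsensusAndMetrics:
    def test_zero_frequencies_give_empty_network(self, toy_pair):
        post = exact_posterior_edges(toy_pair, fan_in=1)
        post.frequency[:] = 0.0
        assert consensus(post).edges == []

    def test_threshold_is_inclusive(self, toy_pair):
        post = exact_posterior_edges(toy_pair, fan_in=1)
        post.frequency[:] = 0.0
        post.frequency[0, 1] = 0.5
        net = consensus(post, 0.5)
        assert ("A", "B") in net

    def test_invalid_threshold_rejected(self, toy_pair):
        post = exact_posterior_edges(toy_pair, fan_in=1)
        with pytest.raises(ValueError, match="threshold"):
            consensus(post, 1.0)

    def test_perfect_prediction_scores_one(self, toy_pair):
        post = exact_posterior_edges(toy_pair, fan_in=1)
        post.frequency[:] = 0.0
        post.frequency[0, 1] = 0.9
        met = recovery_metrics(post, [("A", "B")])
        assert met.precision == met.recall == met.auroc == 1.0

    def test_random_scores_give_chance_auroc(self):
        rng = np.random.default_rng(0)
        value = auroc(rng.random(4000), rng.random(4000))
        assert abs(value - 0.5) < 0.03

    def test_truth_edge_outside_mediators_rejected(self, toy_pair):
        post = exact_posterior_edges(toy_pair, fan_in=1)
        with pytest.raises(ValueError, match="outside"):
            recovery_metrics(post, [("A", "Z")])

    def test_recovery_improves_with_cohort_size_off_ceiling(self):
        # more patients help once the noise level makes the problem hard;
        # at low noise both sizes saturate and the comparison is a coin flip
        truth = [("MCP1", "MCP1"), ("MIG", "MIG"), ("IP10", "IP10"),
                 ("IFNg", "IP10"), ("MCP1", "IL6"), ("MIG", "IL6")]
        byst = ("IL8", "TNFa", "Eotaxin")

        def mean_auroc(n):
            vals = []
            for seed in range(1, 6):
                cohort = generate_cohort(
                    0, 0, n, seed=seed, n_healthy=0,
                    mediator_map=default_mediator_map(sigma=1.2),
                )
                data = transitions(align_panel(cohort))
                post = mh_sample_structures(data, fan_in=3, iters=6000, seed=seed)
                meds = post.mediators
                negs = [(s, t) for s in meds for t in meds
                        if s in byst or t in byst]
                vals.append(recovery_metrics(post, truth, negs).auroc)
            return float(np.mean(vals))

        assert mean_auroc(30) <= mean_auroc(90)
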