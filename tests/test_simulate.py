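"""The synthetic hypermutator-evolution generator: determinism, model
structure, and direction-of-effect recovery."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from mutdens import (
    ConfigError,
    MutationClass,
    PopulationClass,
    SimulationConfig,
    associate,
    degree,
    generate_covariates,
    generate_genome,
    mutation_density,
    simulate_dataset,
    simulate_mutation_tables,
)
from mutdens.io import records_to_frame


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"n_hypermutator": 0},
            {"mu_h": -1e-4},
            {"beta": -1.0},
            {"frac_syn": 1.5},
            {"condition_corr": 2.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        config = SimulationConfig(n_genes=50, beta=1.5, seed=9)
        path = tmp_path / "sim.yaml"
        config.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == config

    def test_unknown_option_rejected(self):
        with pytest.raises(ConfigError, match="mu_x"):
            SimulationConfig.from_dict({"mu_x": 1.0})


class TestGenome:
    def test_seed_determinism_and_count(self):
        config = SimulationConfig(n_genes=10, seed=5)
        assert generate_genome(config) == generate_genome(config)
        assert len(generate_genome(config)) == 10

    def test_lengths_are_positive_codon_multiples(self):
        anns = generate_genome(SimulationConfig(n_genes=500, seed=1))
        lengths = np.array([a.length_nt for a in anns])
        assert (lengths >= 3).all() and (lengths % 3 == 0).all()

    def test_genes_do_not_overlap(self):
        anns = generate_genome(SimulationConfig(n_genes=200, seed=2))
        ordered = sorted(anns, key=lambda a: a.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.end <= b.start


class TestCovariates:
    def test_truth_pi_bounded_and_monotone_in_abundance(self):
        config = SimulationConfig(n_genes=300, beta=2.0, seed=4)
        anns = generate_genome(config)
        _, _, truth = generate_covariates(config, anns)
        z = np.array([truth.z[a.gene_id] for a in anns])
        pi = np.array([truth.pi[a.gene_id] for a in anns])
        assert ((pi >= 0) & (pi <= 1)).all()
        order = np.argsort(z)
        assert (np.diff(pi[order]) >= 0).all()

    def test_beta_zero_gives_constant_removal_probability(self):
        config = SimulationConfig(n_genes=100, beta=0.0, seed=4)
        anns = generate_genome(config)
        _, _, truth = generate_covariates(config, anns)
        assert set(truth.pi.values()) == {0.5}

    def test_perfectly_correlated_conditions_share_ranks(self):
        config = SimulationConfig(n_genes=200, condition_corr=1.0, seed=6)
        anns = generate_genome(config)
        abundances, _, _ = generate_covariates(config, anns)
        a, b = abundances
        genes = [ann.gene_id for ann in anns]
        va = np.array([a.values[g] for g in genes])
        vb = np.array([b.values[g] for g in genes])
        assert (np.argsort(va) == np.argsort(vb)).all()

    def test_decoupled_degree_uncorrelated_with_abundance(self):
        config = SimulationConfig(n_genes=2000, delta=0.0, seed=7)
        anns = generate_genome(config)
        abundances, network, _ = generate_covariates(config, anns)
        from mutdens import spearman_two_sided

        dm = degree(network)
        genes = [a.gene_id for a in anns if a.gene_id in dm]
        rho, _ = spearman_two_sided(
            [abundances[0].values[g] for g in genes], [dm[g] for g in genes]
        )
        assert abs(rho) < 3.0 / np.sqrt(len(genes))  # within the null band

    def test_generated_network_satisfies_handshake(self):
        config = SimulationConfig(n_genes=300, seed=8)
        anns = generate_genome(config)
        _, network, _ = generate_covariates(config, anns)
        dm = degree(network)
        assert sum(dm.values.values()) == 2 * network.n_edges


class TestMutationTables:
    def test_full_determinism(self):
        d1 = simulate_dataset(SimulationConfig(n_genes=150, seed=12))
        d2 = simulate_dataset(SimulationConfig(n_genes=150, seed=12))
        assert d1.records == d2.records
        assert d1.annotations == d2.annotations
        d3 = simulate_dataset(SimulationConfig(n_genes=150, seed=13))
        assert d3.records != d1.records

    def test_zero_rates_give_zero_records(self):
        dataset = simulate_dataset(
            SimulationConfig(n_genes=50, mu_h=0.0, mu_n=0.0, seed=1)
        )
        assert dataset.records == []

    def test_generations_within_horizon(self):
        dataset = simulate_dataset(SimulationConfig(n_genes=200, seed=3))
        horizon = dataset.config.horizon
        assert all(0 < r.generation_observed <= horizon for r in dataset.records)

    def test_neutral_model_count_scales_with_length(self):
        """Closed-form check: with beta=0 (uniform 50% removal of
        nonsynonymous candidates) and gamma=0, the expected observed count
        per gene is n_pops * mu_h * L_g * (frac_syn + (1-frac_syn)/2), so a
        through-origin regression of hypermutator counts on length recovers
        that slope."""
        config = SimulationConfig(n_genes=3000, beta=0.0, gamma=0.0, seed=21)
        dataset = simulate_dataset(config)
        table = mutation_density(
            dataset.records, dataset.annotations, populations="hypermutator",
            scheme="all",
        )
        L = table.frame["length_nt"].to_numpy(float)
        c = table.frame["count"].to_numpy(float)
        slope = (c * L).sum() / (L * L).sum()
        expected = (
            config.n_hypermutator
            * config.mu_h
            * (config.frac_syn + (1 - config.frac_syn) * 0.5)
        )
        # Poisson sampling error of the through-origin estimator
        se = np.sqrt((expected * L**3).sum()) / (L * L).sum()
        assert slope == pytest.approx(expected, abs=4 * se)

    def test_strong_selection_depletes_abundant_genes(self):
        config = SimulationConfig(n_genes=2000, beta=5.0, seed=22)
        dataset = simulate_dataset(config)
        table = mutation_density(
            dataset.records, dataset.annotations, populations="hypermutator",
            scheme="nonsynonymous",
        )
        genes = [a.gene_id for a in dataset.annotations]
        abundance = np.array([dataset.abundances[0].values[g] for g in genes])
        dens = table.densities.loc[genes].to_numpy()
        deciles = np.quantile(abundance, [0.1, 0.9])
        bottom = dens[abundance <= deciles[0]].mean()
        top = dens[abundance >= deciles[1]].mean()
        assert top < bottom

    def test_synonymous_bias_renormalization_keeps_total_fixed(self):
        """The genome-wide expected synonymous count is independent of
        gamma; only its distribution across genes shifts."""
        totals = {}
        for gamma in (0.0, 3.0):
            counts = []
            config = SimulationConfig(n_genes=2000, gamma=gamma, seed=30)
            anns = generate_genome(config)
            _, _, truth = generate_covariates(config, anns)
            for k in range(10):
                records = simulate_mutation_tables(config, anns, truth, seed=400 + k)
                counts.append(
                    sum(
                        r.mutation_class is MutationClass.SYNONYMOUS
                        for r in records
                        if r.population_class is PopulationClass.HYPERMUTATOR
                    )
                )
            totals[gamma] = np.mean(counts)
        # equal expectation up to Monte-Carlo noise (~1.5% here)
        assert totals[3.0] == pytest.approx(totals[0.0], rel=0.05)

    def test_missense_nonsense_split(self):
        dataset = simulate_dataset(SimulationConfig(n_genes=2000, seed=31))
        n_mis = sum(r.mutation_class is MutationClass.MISSENSE for r in dataset.records)
        n_non = sum(r.mutation_class is MutationClass.NONSENSE for r in dataset.records)
        frac = n_mis / (n_mis + n_non)
        assert frac == pytest.approx(0.9, abs=0.03)


class TestPipelineDirections:
    """Direction-of-effect recovery through the full density -> associate
    pipeline, at reduced size (full-size versions live in the acceptance
    suite)."""

    def test_selection_produces_anticorrelation_and_syn_bias_positive(self):
        dataset = simulate_dataset(SimulationConfig(n_genes=1500, seed=40))
        nonsyn = mutation_density(
            dataset.records, dataset.annotations, populations="hypermutator",
            scheme="nonsynonymous",
        )
        syn = mutation_density(
            dataset.records, dataset.annotations, populations="hypermutator",
            scheme="synonymous",
        )
        abundance = dataset.abundances[0]
        assert associate(nonsyn, abundance).rho < 0
        assert associate(syn, abundance).rho > 0
        assert associate(nonsyn, degree(dataset.network)).rho < 0

    def test_zeros_exclusion_strengthens_anticorrelation_on_average(self):
        """In this model the zeros-excluded |rho| exceeds the zeros-included
        |rho| in expectation (zero-count genes are dominated by short genes
        whose density rank is noise), though not in every replicate."""
        config = SimulationConfig(seed=0)
        anns = generate_genome(config)
        abundances, _, truth = generate_covariates(config, anns)
        deltas = []
        for k in range(15):
            frame = records_to_frame(
                simulate_mutation_tables(config, anns, truth, seed=9000 + k)
            )
            table = mutation_density(
                frame, anns, populations="hypermutator", scheme="all"
            )
            inc = associate(table, abundances[0], zeros="include")
            exc = associate(table, abundances[0], zeros="exclude")
            deltas.append(abs(exc.rho) - abs(inc.rho))
        assert np.mean(deltas) > 0

    def test_cumulative_correlation_strengthens_over_time(self):
        """Under stationary accrual the cumulative |rho| rises with the
        generation cutoff (more mutations, same underlying effect)."""
        config = SimulationConfig(n_genes=2000, seed=41)
        dataset = simulate_dataset(config)
        from mutdens import correlation_time_course, cumulative_series

        series = cumulative_series(
            dataset.records, dataset.annotations, populations="hypermutator",
            scheme="nonsynonymous",
        )
        course = correlation_time_course(series, dataset.abundances[0])
        magnitudes = [abs(r.rho) for r in course]
        # allow small Monte-Carlo wiggles between adjacent cutoffs
        assert all(b >= a - 0.02 for a, b in zip(magnitudes, magnitudes[1:]))
        assert magnitudes[-1] > magnitudes[0]
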