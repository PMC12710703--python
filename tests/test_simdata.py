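"""Forward simulator: demographic model construction, rescaling, neutral
theory oracles, DFE plumbing, artifacts and catch series."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from genoerode import simdata as sd
from genoerode.core import HET, MISSING

from conftest import (
    TINY_GENOME,
    TINY_MU,
    TINY_N,
    closed_form_bottleneck_loss,
    exact_neutral_loss,
)


# ---------------------------------------------------------------------------
# demography and rescaling
# ---------------------------------------------------------------------------

class TestDemographyModel:
    def test_whaling_bottleneck_epochs(self):
        dem = sd.bottleneck_demography()
        assert len(dem.epochs) == 3
        burn, crash, recovery = dem.epochs
        assert (burn.duration, burn.n_start, burn.n_end) == (500_000, 16_000, 16_000)
        assert (crash.n_start, crash.n_end, crash.duration) == (16_000, 375, 5)
        assert (recovery.n_start, recovery.n_end, recovery.duration) == (375, 8_000, 10)
        assert crash.duration + recovery.duration == 15

    def test_exponential_epoch_interpolates_geometrically(self):
        crash = sd.bottleneck_demography().epochs[1]
        sizes = crash.sizes()
        ratio = (375 / 16_000) ** (1 / 5)
        expected = [round(16_000 * ratio**t) for t in range(1, 6)]
        expected[-1] = 375
        assert sizes.tolist() == expected
        # geometric: successive ratios nearly constant
        r = sizes[1:] / sizes[:-1].astype(float)
        assert np.allclose(r, r[0], rtol=0.01)

    def test_invalid_epochs_rejected(self):
        with pytest.raises(ValueError):
            sd.Epoch(0, 100, 100)
        with pytest.raises(ValueError):
            sd.Epoch(10, 1, 100, "exponential")
        with pytest.raises(ValueError):
            sd.Epoch(10, 50, 100, "constant")


class TestRescaling:
    def test_lambda_one_is_identity(self):
        dem = sd.DemographyModel((sd.Epoch(200, 100, 100, "constant"),))
        model = sd.rescale_model(dem, sd.DFEModel(), sd.GenomeModel(), 1.0)
        assert model.demography == dem
        assert model.epoch_scale == (1.0,)
        assert model.mu_burnin == sd.GenomeModel().mu

    def test_lambda_twenty_arithmetic(self):
        model = sd.rescale_model(
            sd.bottleneck_demography(), sd.DFEModel(), sd.GenomeModel(), 20.0
        )
        burn = model.demography.epochs[0]
        assert (burn.duration, burn.n_start) == (25_000, 800)
        assert model.mu_burnin == pytest.approx(2.24e-7)
        assert model.mean_s_burnin == pytest.approx(-0.2)
        # bottleneck epochs keep natural sizes and durations by default
        assert model.demography.epochs[1:] == sd.bottleneck_demography().epochs[1:]
        assert model.epoch_scale == (20.0, 1.0, 1.0)

    def test_scale_bottleneck_opt_in(self):
        model = sd.rescale_model(
            sd.bottleneck_demography(), sd.DFEModel(), sd.GenomeModel(), 20.0,
            scale_bottleneck=True,
        )
        assert model.demography.epochs[1].n_end == round(375 / 20)
        assert model.epoch_scale == (20.0, 20.0, 20.0)

    def test_rejects_tiny_populations(self):
        dem = sd.DemographyModel((sd.Epoch(10_000, 20, 20, "constant"),))
        with pytest.raises(ValueError):
            sd.rescale_model(dem, sd.DFEModel(), sd.GenomeModel(), 20.0)

    def test_rescaled_equilibrium_matches_unscaled_expectation(self):
        """Burn-in rescaling preserves theta: heterozygosity after a
        rescaled burn-in matches theta/(1+theta) computed with the
        *unscaled* N and mu, within 3 SE over 20 replicates."""
        dem = sd.DemographyModel((sd.Epoch(4000, 200, 200, "constant"),))
        genome = sd.GenomeModel(**TINY_GENOME)
        model = sd.rescale_model(dem, sd.neutral_dfe(), genome, 2.0)
        hets = [
            sd.simulate_rescaled(model, sample_size=10, seed=300 + i)
            .summaries["cohorts"]["final"]["mean_het"]
            for i in range(20)
        ]
        theta = 4 * 200 * TINY_MU
        expected = theta / (1 + theta)
        se = np.std(hets, ddof=1) / np.sqrt(len(hets))
        assert abs(np.mean(hets) - expected) < 3 * se


# ---------------------------------------------------------------------------
# neutral theory oracles
# ---------------------------------------------------------------------------

class TestNeutralTheory:
    def test_no_mutation_no_variation(self):
        dem = sd.DemographyModel((sd.Epoch(50, 40, 40, "constant"),))
        genome = sd.GenomeModel(n_genes=10, gene_length=100, n_chromosomes=2, mu=0.0)
        rep = sd.simulate_replicate(dem, sd.DFEModel(), genome, sample_size=5, seed=1)
        assert len(rep.sites) == 0
        assert rep.summaries["cohorts"]["final"]["mean_het"] == 0.0

    def test_equilibrium_heterozygosity(self, neutral_equilibrium_reps):
        """Mean per-site heterozygosity ~ theta/(1+theta) within 3 SE."""
        hets = [
            r.summaries["cohorts"]["final"]["mean_het"]
            for r in neutral_equilibrium_reps
        ]
        theta = 4 * TINY_N * TINY_MU
        expected = theta / (1 + theta)
        se = np.std(hets, ddof=1) / np.sqrt(len(hets))
        assert abs(np.mean(hets) - expected) < 3 * se

    def test_bottleneck_loss_matches_drift_decay(
        self, bottleneck_neutral_reps, bottleneck_demography_small
    ):
        """Heterozygosity loss through the crash matches
        1 - prod(1 - 1/(2*N_t)) within 3 SE; the exact recursion with
        new-mutation input must agree at least as well."""
        losses = [r.summaries["het_loss_pct"] / 100 for r in bottleneck_neutral_reps]
        se = np.std(losses, ddof=1) / np.sqrt(len(losses))
        drift_only = closed_form_bottleneck_loss(bottleneck_demography_small)
        assert abs(np.mean(losses) - drift_only) < 3 * se
        exact = exact_neutral_loss(bottleneck_demography_small, TINY_MU)
        assert abs(np.mean(losses) - exact) < 3 * se


# ---------------------------------------------------------------------------
# replicate mechanics
# ---------------------------------------------------------------------------

class TestReplicateMechanics:
    def test_same_seed_bit_identical(self):
        dem = sd.DemographyModel((sd.Epoch(300, 60, 60, "constant"),))
        genome = sd.GenomeModel(**TINY_GENOME)
        a = sd.simulate_replicate(dem, sd.DFEModel(), genome, sample_size=8, seed=4)
        b = sd.simulate_replicate(dem, sd.DFEModel(), genome, sample_size=8, seed=4)
        assert a.sites.equals(b.sites)
        for label in a.cohorts:
            assert a.cohorts[label].matrix.equals(b.cohorts[label].matrix)
        assert a.summaries == b.summaries

    def test_different_seeds_differ(self):
        dem = sd.DemographyModel((sd.Epoch(300, 60, 60, "constant"),))
        genome = sd.GenomeModel(**TINY_GENOME)
        a = sd.simulate_replicate(dem, sd.DFEModel(), genome, sample_size=8, seed=4)
        b = sd.simulate_replicate(dem, sd.DFEModel(), genome, sample_size=8, seed=5)
        assert not a.sites.equals(b.sites)

    def test_summaries_recompute_identically(self, bottleneck_neutral_reps):
        rep = bottleneck_neutral_reps[0]
        re = rep.recompute_summaries()
        for label, stored in rep.summaries["cohorts"].items():
            assert re["cohorts"][label] == stored
        assert re["het_loss_pct"] == rep.summaries["het_loss_pct"]

    def test_sample_size_validation(self):
        dem = sd.DemographyModel((sd.Epoch(10, 8, 8, "constant"),))
        genome = sd.GenomeModel(**TINY_GENOME)
        with pytest.raises(ValueError, match="sample_size"):
            sd.simulate_replicate(dem, sd.DFEModel(), genome, sample_size=9, seed=1)
        with pytest.raises(ValueError, match="timepoint"):
            sd.simulate_replicate(
                dem, sd.DFEModel(), genome, sample_size=4, timepoints={}, seed=1
            )

    def test_mean_fitness_declines_with_stronger_selection(self):
        """More negative mean s => lower mean fitness (3-point grid,
        averaged over paired seeds)."""
        dem = sd.DemographyModel((sd.Epoch(500, 60, 60, "constant"),))
        genome = sd.GenomeModel(n_genes=20, gene_length=500, n_chromosomes=2, mu=2e-6)
        means = []
        for mean_s in (-0.001, -0.01, -0.05):
            dfe = sd.DFEModel(p_neutral=0.2, mean_s=mean_s, gamma_shape=0.5)
            w = [
                sd.simulate_replicate(dem, dfe, genome, sample_size=10, seed=70 + k)
                .summaries["cohorts"]["final"]["mean_fitness"]
                for k in range(5)
            ]
            means.append(np.mean(w))
        assert means[0] >= means[1] >= means[2]


# ---------------------------------------------------------------------------
# impact categories
# ---------------------------------------------------------------------------

class TestImpactCategories:
    def test_boundary_values(self):
        labels = sd.assign_impact_categories(
            np.array([0.0, -0.5, -5e-5, -5e-3]), seed=0, neutral_low_fraction=0.0
        )
        assert labels[0] == "MODIFIER"  # neutral with LOW fraction zero
        assert labels[1] == "HIGH"
        assert labels[2] == "LOW"
        assert labels[3] == "MODERATE"

    def test_neutral_split_is_seeded_half_half(self):
        labels = sd.assign_impact_categories(np.zeros(10_000), seed=3)
        frac_low = np.mean(labels == "LOW")
        assert abs(frac_low - 0.5) < 0.02
        again = sd.assign_impact_categories(np.zeros(10_000), seed=3)
        assert (labels == again).all()

    def test_category_counts_match_dfe_mass(self):
        """Binning 10,000 DFE draws through the classifier equals direct
        brute-force binning of the same sample."""
        rng = np.random.default_rng(11)
        dfe = sd.DFEModel()
        s = np.where(
            rng.random(10_000) < dfe.p_neutral,
            0.0,
            -rng.gamma(dfe.gamma_shape, dfe.gamma_scale, size=10_000),
        )
        labels = sd.assign_impact_categories(s, seed=5)
        a = np.abs(s)
        expected = {
            "MODERATE": int(((a > 1e-4) & (a <= 1e-2)).sum()),
            "HIGH": int((a > 1e-2).sum()),
        }
        assert int((labels == "MODERATE").sum()) == expected["MODERATE"]
        assert int((labels == "HIGH").sum()) == expected["HIGH"]
        # neutral sites split between LOW and MODIFIER; selected LOW adds on
        n_neutral = int((s == 0).sum())
        n_sel_low = int(((a > 0) & (a <= 1e-4)).sum())
        assert int((labels == "LOW").sum()) + int((labels == "MODIFIER").sum()) == (
            n_neutral + n_sel_low
        )

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError):
            sd.assign_impact_categories(np.array([-0.1]), thresholds=(1e-2, 1e-4))


# ---------------------------------------------------------------------------
# read depths and deamination artifacts
# ---------------------------------------------------------------------------

class TestArtifacts:
    def test_rate_zero_leaves_sites_unchanged(self):
        matrix, sites = sd.synthetic_cohort(500, 8, seed=1)
        out, sites2 = sd.add_historical_artifacts(matrix, sites, 0.0, seed=2)
        assert len(sites2) == len(sites)
        assert not sites2["is_artifact"].any()
        assert out.dp is not None and out.has_allelic_depths()

    def test_injected_sites_are_low_count_transitions(self, artifact_fixture):
        merged, sites = artifact_fixture
        art = sites["is_artifact"].to_numpy(dtype=bool)
        assert art.sum() > 100
        assert sites.loc[art, "is_transition"].all()
        counts = merged.alt_allele_counts()
        assert (counts[art] <= 2).all()
        assert (counts[art] >= 1).all()

    def test_depth_model(self):
        matrix, sites = sd.synthetic_cohort(2000, 10, seed=3)
        out = sd.attach_read_depths(matrix, target_depth=6.0, seed=4)
        called = out.gt != MISSING
        assert abs(out.dp[called].mean() - 6.0) < 0.2
        het = out.gt == HET
        # heterozygote allelic depths sum to DP and average half
        assert (out.ad_ref[het] + out.ad_alt[het] == out.dp[het]).all()
        assert abs(out.ad_alt[het].mean() - 3.0) < 0.2


# ---------------------------------------------------------------------------
# catch series
# ---------------------------------------------------------------------------

class TestCatchSeries:
    def test_constant_census_no_catches(self):
        df = sd.generate_catch_series([500, 500, 500])
        assert (df["catches"] == 0).all()

    def test_pure_decline_catches_equal_drops(self):
        df = sd.generate_catch_series([1000, 900, 800])
        assert df["catches"].tolist() == [100.0, 100.0]
        assert df["cumulative"].tolist() == [100.0, 200.0]

    def test_cumulative_monotone_under_noise(self):
        rng_traj = np.random.default_rng(0).integers(100, 1000, size=30)
        df = sd.generate_catch_series(rng_traj, reporting_noise=0.5, seed=9)
        assert (np.diff(df["cumulative"]) >= 0).all()
        assert (df["catches"] >= 0).all()

    def test_negative_census_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_catch_series([100, -5])


# ---------------------------------------------------------------------------
# config round-trip
# ---------------------------------------------------------------------------

def test_models_round_trip_through_plain_dict():
    import yaml

    dem = sd.bottleneck_demography()
    dfe = sd.DFEModel(p_neutral=0.25, mean_s=-0.02)
    genome = sd.GenomeModel(n_genes=100, mu=3e-8)
    blob = yaml.safe_dump(sd.models_to_dict(dem, dfe, genome))
    dem2, dfe2, genome2 = sd.models_from_dict(yaml.safe_load(blob))
    assert dem2 == dem and dfe2 == dfe and genome2 == genome
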