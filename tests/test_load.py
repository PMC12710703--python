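"""Polarization, potential/realized load, R_x/y with jackknife, and the
Mann-Whitney cohort comparison (exact vs permutation oracle)."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from genoerode import load as ld
from genoerode import simdata as sd
from genoerode.core import GenotypeMatrix, make_site_table


def _polarized_from_freqs(fx, fy, nx=20, ny=20, category="MODERATE", chroms=None):
    """Build a PolarizedSiteSet whose cohort frequencies are exactly fx, fy.

    Cohort x occupies the first nx//2 samples. Frequencies must be
    multiples of 1/nx (resp. 1/ny) in gene copies.
    """
    fx = np.asarray(fx, dtype=float)
    fy = np.asarray(fy, dtype=float)
    n_sites = len(fx)
    sx, sy = nx // 2, ny // 2
    dosage = np.zeros((sx + sy, n_sites), dtype=np.int8)
    for j, (a, b) in enumerate(zip(fx, fy)):
        cx = round(a * nx)
        cy = round(b * ny)
        for block, count, offset in ((0, cx, 0), (1, cy, sx)):
            full, rem = divmod(count, 2)
            for i in range(full):
                dosage[offset + i, j] = 2
            if rem:
                dosage[offset + full, j] = 1
    chroms = chroms if chroms is not None else ["chr1"] * n_sites
    sites = make_site_table(
        chrom=chroms, pos=np.arange(1, n_sites + 1) * 10,
        ref=["A"] * n_sites, alt=["C"] * n_sites,
        impact=np.full(n_sites, category, dtype=object),
    )
    sites["derived"] = "alt"
    samples = [f"X{i}" for i in range(sx)] + [f"Y{i}" for i in range(sy)]
    pol = ld.PolarizedSiteSet(
        sites=sites, derived_dosage=dosage, samples=samples, n_dropped=0
    )
    cohorts = pd.Series(
        {s: ("x" if s.startswith("X") else "y") for s in samples}
    )
    return pol, cohorts


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

class TestPolarize:
    def _one_site(self, gt_col, ref="A", alt="C", outgroup="A"):
        n = len(gt_col)
        matrix = GenotypeMatrix(
            samples=[f"S{i}" for i in range(n)],
            gt=np.asarray(gt_col, dtype=np.int8)[:, None],
        )
        sites = make_site_table(chrom=["chr1"], pos=[1], ref=[ref], alt=[alt])
        return matrix, sites, np.array([outgroup], dtype=object)

    def test_high_frequency_ref_plus_outgroup_match(self):
        # ref frequency 0.975 (one het among 20 copies), outgroup = ref
        matrix, sites, og = self._one_site([0] * 19 + [1], outgroup="A")
        pol = ld.polarize(matrix, sites, og)
        assert len(pol.sites) == 1
        assert pol.sites.loc[0, "derived"] == "alt"
        assert pol.derived_dosage[-1, 0] == 1

    def test_outgroup_mismatch_drops_site(self):
        matrix, sites, og = self._one_site([0] * 19 + [1], outgroup="C")
        pol = ld.polarize(matrix, sites, og)
        assert len(pol.sites) == 0
        assert pol.n_dropped == 1

    def test_intermediate_frequency_dropped(self):
        matrix, sites, og = self._one_site([1] * 20, outgroup="A")
        pol = ld.polarize(matrix, sites, og)  # f_alt = 0.5: nothing > 0.95
        assert pol.n_dropped == 1

    def test_alt_can_be_ancestral(self):
        matrix, sites, og = self._one_site([2] * 19 + [1], outgroup="C")
        pol = ld.polarize(matrix, sites, og)
        assert pol.sites.loc[0, "derived"] == "ref"
        # dosage flipped: the het carries one derived (ref) copy
        assert pol.derived_dosage[-1, 0] == 1
        assert (pol.derived_dosage[:-1, 0] == 0).all()

    def test_error_rate_below_five_percent_on_simulated_truth(self):
        """With a slightly diverged outgroup, the polarization rule calls
        the wrong allele derived at under 5% of retained sites (ground
        truth: the generator's reference allele is ancestral).  The cohort
        must exceed 10 diploids - with 20 gene copies no polymorphic site
        can clear the 0.95 frequency bar."""
        matrix, sites = sd.synthetic_cohort(8000, 15, seed=21)
        og = sd.outgroup_alleles(sites, divergence=0.02, seed=22)
        pol = ld.polarize(matrix, sites, og)
        n_kept = len(pol.sites)
        n_err = int((pol.sites["derived"] == "ref").sum())
        assert n_kept > 100
        assert n_err / n_kept < 0.05


# ---------------------------------------------------------------------------
# per-sample load
# ---------------------------------------------------------------------------

class TestLoadPerSample:
    def test_mixed_genotypes_arithmetic(self):
        # one sample: het, hom-derived, hom-ancestral -> potential 2,
        # realized 0.5
        pol, _ = _polarized_from_freqs([0.05, 0.1, 0.0], [0, 0, 0], nx=20, ny=2)
        pol.derived_dosage[0] = [1, 2, 0]
        df = ld.load_per_sample(pol, category="MODERATE")
        row = df[df["sample_id"] == pol.samples[0]].iloc[0]
        assert row["potential"] == 2
        assert row["realized"] == pytest.approx(0.5)

    def test_all_homozygous_realized_one(self):
        pol, _ = _polarized_from_freqs([0.1, 0.1], [0, 0])
        pol.derived_dosage[0] = [2, 2]
        df = ld.load_per_sample(pol, category="MODERATE")
        assert df[df["sample_id"] == pol.samples[0]]["realized"].iloc[0] == 1.0

    def test_zero_potential_is_missing(self):
        pol, _ = _polarized_from_freqs([0.05], [0.0])
        df = ld.load_per_sample(pol, category="MODERATE")
        empty = df[(df["potential"] == 0)]
        assert empty["realized"].isna().all()

    def test_realized_load_rises_after_bottleneck_in_most_replicates(self):
        """Directional: mean realized load of moderately deleterious sites
        is at least the pre-crash cohort's in >= 50% of 20 replicates."""
        dem = sd.DemographyModel(
            (
                sd.Epoch(1500, 120, 120, "constant"),
                sd.Epoch(5, 120, 10, "exponential"),
                sd.Epoch(10, 10, 80, "exponential"),
            )
        )
        genome = sd.GenomeModel(n_genes=20, gene_length=500, n_chromosomes=4, mu=4e-6)
        dfe = sd.DFEModel(p_neutral=0.3, mean_s=-0.005, gamma_shape=0.5)
        wins = ties_ok = 0
        n_reps = 20
        for i in range(n_reps):
            rep = sd.simulate_replicate(dem, dfe, genome, sample_size=10,
                                        seed=8100 + i)
            merged = rep.cohorts["pre_bottleneck"].matrix
            post = rep.cohorts["post_recovery"].matrix
            from genoerode.core import concat_samples

            both = concat_samples(merged, post)
            og = sd.outgroup_alleles(rep.sites, divergence=0.0, seed=0)
            pol = ld.polarize(both, rep.sites, og)
            df = ld.load_per_sample(pol, category="MODERATE")
            df["cohort"] = ["pre"] * merged.n_samples + ["post"] * post.n_samples
            means = df.groupby("cohort")["realized"].mean()
            if np.isnan(means.get("pre", np.nan)) or np.isnan(means.get("post", np.nan)):
                ties_ok += 1  # no informative sites in this replicate
            elif means["post"] >= means["pre"]:
                wins += 1
        assert wins + ties_ok >= n_reps // 2


# ---------------------------------------------------------------------------
# R_x/y
# ---------------------------------------------------------------------------

class TestRxy:
    def test_identical_cohorts_give_one(self):
        freqs = [0.05, 0.1, 0.15, 0.2]
        pol, cohorts = _polarized_from_freqs(freqs, freqs)
        r = ld.rxy(pol, cohorts, "x", "y", "MODERATE")
        assert r.estimate == pytest.approx(1.0)

    def test_hand_computed_single_site(self):
        # f_x = 0.5, f_y = 0.1: L_xy = 0.45, L_yx = 0.05, R = 9
        pol, cohorts = _polarized_from_freqs([0.5], [0.1])
        r = ld.rxy(pol, cohorts, "x", "y", "MODERATE")
        assert r.estimate == pytest.approx(9.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_inversion_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 15))
        fx = rng.integers(0, 21, size=n) / 20
        fy = rng.integers(0, 21, size=n) / 20
        keep = (fx + fy) > 0
        if not keep.any() or fx[keep].sum() == 0 or fy[keep].sum() == 0:
            return
        pol, cohorts = _polarized_from_freqs(fx, fy)
        try:
            fwd = ld.rxy(pol, cohorts, "x", "y", "MODERATE").estimate
            rev = ld.rxy(pol, cohorts, "y", "x", "MODERATE").estimate
        except ValueError:
            return  # degenerate (a zero L sum): undefined ratio
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_jackknife_block_without_category_sites_is_neutral(self):
        """Deleting a chromosome carrying no category sites reproduces the
        full estimate exactly."""
        fx = [0.3, 0.2, 0.1]
        fy = [0.1, 0.25, 0.3]
        pol, cohorts = _polarized_from_freqs(
            fx, fy, chroms=["chr1", "chr1", "chr2"]
        )
        # chr3 exists in the data but has only LOW-impact sites
        extra, _ = _polarized_from_freqs([0.2], [0.2], category="LOW",
                                         chroms=["chr3"])
        pol.sites = pd.concat([pol.sites, extra.sites], ignore_index=True)
        pol.derived_dosage = np.hstack([pol.derived_dosage, extra.derived_dosage])
        full = ld.rxy(pol, cohorts, "x", "y", "MODERATE")
        # manual delete-chr3 replicate equals the estimate
        on = pol.sites["impact"].to_numpy() == "MODERATE"
        assert full.estimate == pytest.approx(
            ld.rxy(
                ld.PolarizedSiteSet(
                    pol.sites[on].reset_index(drop=True),
                    pol.derived_dosage[:, on], pol.samples, 0,
                ),
                cohorts, "x", "y", "MODERATE",
            ).estimate
        )

    def test_ci_covers_one_for_same_generation_cohorts(self):
        """Two cohorts drawn from the same generation are exchangeable:
        the 95% jackknife CI covers R = 1 in >= 90% of replicates."""
        dem = sd.DemographyModel((sd.Epoch(1500, 100, 100, "constant"),))
        genome = sd.GenomeModel(n_genes=24, gene_length=500, n_chromosomes=8,
                                mu=4e-6)
        covered = 0
        n_reps = 10
        for i in range(n_reps):
            rep = sd.simulate_replicate(
                dem, sd.neutral_dfe(), genome, sample_size=10,
                timepoints={"a": 0, "b": 0}, seed=8200 + i,
            )
            from genoerode.core import concat_samples

            both = concat_samples(rep.cohorts["a"].matrix, rep.cohorts["b"].matrix)
            samples_a = rep.cohorts["a"].matrix.samples
            cohorts = pd.Series(
                {s: ("a" if s in samples_a else "b") for s in both.samples}
            )
            og = sd.outgroup_alleles(rep.sites, divergence=0.0, seed=0)
            pol = ld.polarize(both, rep.sites, og)
            cats = pol.sites["impact"].value_counts()
            cat = cats.index[0]
            r = ld.rxy(pol, cohorts, "a", "b", cat)
            if r.ci_low <= 1.0 <= r.ci_high:
                covered += 1
        assert covered >= int(0.9 * n_reps)

    def test_undefined_ratio_raises(self):
        pol, cohorts = _polarized_from_freqs([0.2], [0.0])
        with pytest.raises(ValueError, match="L_y,x"):
            ld.rxy(pol, cohorts, "x", "y", "MODERATE")


# ---------------------------------------------------------------------------
# Mann-Whitney comparison
# ---------------------------------------------------------------------------

class TestCompareCohorts:
    def test_identical_samples_p_one(self):
        u, p = ld.compare_cohorts([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_fully_separated_triples(self):
        # {1,2,3} vs {4,5,6}: U = 0; exact two-sided p = 2/20 = 0.1
        u, p = ld.compare_cohorts([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            xs = rng.normal(size=6)
            ys = rng.normal(0.8, size=5)
            _, p = ld.compare_cohorts(xs, ys)
            ref = stats.mannwhitneyu(xs, ys, alternative="two-sided",
                                     method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_matches_permutation_enumeration_with_ties(self):
        """Brute-force oracle: enumerate every labelling of the pooled
        values (including tied data) and count deviations at least as
        extreme."""
        xs = np.array([1.0, 2.0, 2.0, 5.0])
        ys = np.array([2.0, 3.0, 4.0])
        u_obs, p = ld.compare_cohorts(xs, ys)
        pooled = np.concatenate([xs, ys])
        mu = len(xs) * len(ys) / 2
        count = total = 0
        for combo in itertools.combinations(range(len(pooled)), len(xs)):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(combo)] = True
            u = sum(
                np.sum(xv > pooled[~mask]) + 0.5 * np.sum(xv == pooled[~mask])
                for xv in pooled[mask]
            )
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=0.01)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(9)
        xs = rng.normal(size=30)
        ys = rng.normal(0.5, size=25)
        _, p = ld.compare_cohorts(xs, ys)
        ref = stats.mannwhitneyu(xs, ys, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert p == pytest.approx(ref)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            ld.compare_cohorts([], [1.0])
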