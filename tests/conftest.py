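"""Shared fixtures: small forward-simulation runs reused across test
modules.  Everything is seeded; session scope keeps the expensive runs to
one execution."""

from __future__ import annotations

import numpy as np
import pytest

from genoerode import simdata as sd


TINY_N = 100
TINY_MU = 1e-5          # theta = 4*N*mu = 0.004 per site
TINY_GENOME = dict(n_genes=20, gene_length=500, n_chromosomes=2, mu=TINY_MU)


@pytest.fixture(scope="session")
def neutral_equilibrium_reps():
    """20 neutral replicates at mutation-drift equilibrium.

    Constant N=100, theta = 4*N*mu = 0.004 per site, 20 generations of
    burn-in per coalescent time unit (2000 total)."""
    dem = sd.DemographyModel((sd.Epoch(2000, TINY_N, TINY_N, "constant"),))
    genome = sd.GenomeModel(**TINY_GENOME)
    return [
        sd.simulate_replicate(
            dem, sd.neutral_dfe(), genome, sample_size=10, seed=9000 + i
        )
        for i in range(20)
    ]


BOTTLENECK_EPOCHS = (
    sd.Epoch(6000, 300, 300, "constant"),
    sd.Epoch(5, 300, 12, "exponential"),
    sd.Epoch(10, 12, 200, "exponential"),
)


@pytest.fixture(scope="session")
def bottleneck_neutral_reps():
    """20 neutral replicates through a deep crash-and-recovery.

    Equilibrated N=300, exponential crash to 12 over 5 generations,
    recovery to 200 over 10 - a desk-scale analogue of the whaling
    bottleneck deep enough that drift decay dominates the small
    new-mutation input over the 15 bottleneck generations."""
    dem = sd.DemographyModel(BOTTLENECK_EPOCHS)
    genome = sd.GenomeModel(**TINY_GENOME)
    return [
        sd.simulate_replicate(
            dem, sd.neutral_dfe(), genome, sample_size=12, seed=5000 + i
        )
        for i in range(20)
    ]


@pytest.fixture(scope="session")
def bottleneck_demography_small():
    return sd.DemographyModel(BOTTLENECK_EPOCHS)


@pytest.fixture(scope="session")
def artifact_fixture():
    """10,000-site cohort with injected deamination-style artifacts."""
    matrix, sites = sd.synthetic_cohort(10_000, 10, seed=77)
    merged, sites2 = sd.add_historical_artifacts(
        matrix, sites, deamination_rate=0.05, target_depth=6.0, seed=78
    )
    return merged, sites2


def closed_form_bottleneck_loss(demography: sd.DemographyModel) -> float:
    """Expected neutral heterozygosity loss over the post-burn-in epochs:
    1 - prod_t (1 - 1/(2*N_t)).

    Two lineages sampled in generation t coalesce among the *parents*, so
    the product runs over the parental sizes: the burn-in size enters once
    and the final generation's size not at all."""
    sizes = np.concatenate([e.sizes() for e in demography.epochs[1:]]).astype(float)
    parents = np.concatenate([[demography.epochs[0].n_end], sizes[:-1]])
    return 1.0 - np.prod(1.0 - 1.0 / (2.0 * parents))


def exact_neutral_loss(demography: sd.DemographyModel, mu_per_site: float) -> float:
    """Exact expected loss including new-mutation input:
    pi_{t+1} = pi_t * (1 - 1/(2*N_t^parent)) + 2*mu, from the burn-in
    equilibrium pi_0 = 4*N*mu."""
    n_burn = demography.epochs[0].n_end
    pi = pi0 = 4.0 * n_burn * mu_per_site
    sizes = np.concatenate([e.sizes() for e in demography.epochs[1:]]).astype(float)
    parents = np.concatenate([[n_burn], sizes[:-1]])
    for n in parents:
        pi = pi * (1.0 - 1.0 / (2.0 * n)) + 2.0 * mu_per_site
    return 1.0 - pi / pi0
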