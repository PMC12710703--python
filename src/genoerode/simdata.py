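"""Forward Wright-Fisher simulation with a deleterious DFE, plus synthetic
fixtures for every downstream stage.

The simulator models a diploid, randomly mating population whose genome is
a set of genes (free recombination between genes, complete linkage within
a gene).  New mutations arise at a per-bp rate and draw a selection
coefficient from a distribution of fitness effects (DFE): neutral with
probability ``p_neutral``, otherwise deleterious with ``s`` drawn from a
(negated) gamma distribution.  Fitness is multiplicative across sites with
heterozygote effect ``1 + h*s`` and homozygote effect ``1 + s``, floored
at zero.

Demography is an ordered list of epochs; population-size rescaling at a
factor ``lambda`` (burn-in only by default) divides the burn-in size and
duration by ``lambda`` while multiplying the mutation rate and selection
coefficients by ``lambda`` *within that epoch*, preserving the population
mutation rate ``4*N*mu`` and scaled selection ``2*N*s``.  Bottleneck and
recovery epochs run in natural generations at natural size so that drift
per calendar generation is untouched.

The module also fabricates the ancillary inputs of a temporal
(museum-vs-modern) genomic study: per-genotype read depths, spurious
end-of-read deamination-style transitions in the historical cohort,
outgroup alleles for ancestral polarization, catch series, and
Ne-trajectory run tables in the dialect of an LD-based estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _wf
from .core import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, make_site_table

IMPACT_LEVELS = ("MODIFIER", "LOW", "MODERATE", "HIGH")

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = np.array(["A", "C", "G", "T"])
_TRANSVERSION_PARTNERS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


# ---------------------------------------------------------------------------
# domain models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Epoch:
    """One demographic epoch: ``duration`` offspring generations during which
    the diploid size moves from ``n_start`` to ``n_end``."""

    duration: int
    n_start: int
    n_end: int
    shape: str = "constant"  # "constant" | "exponential"

    def __post_init__(self) -> None:
        if int(self.duration) != self.duration or self.duration < 1:
            raise ValueError("epoch duration must be an integer >= 1")
        if self.n_start < 2 or self.n_end < 2:
            raise ValueError("population size must be >= 2")
        if self.shape not in ("constant", "exponential"):
            raise ValueError(f"unknown epoch shape {self.shape!r}")
        if self.shape == "constant" and self.n_start != self.n_end:
            raise ValueError("constant epoch requires n_start == n_end")

    def sizes(self) -> np.ndarray:
        """Diploid size of each offspring generation in the epoch.

        Exponential epochs interpolate geometrically; the final generation
        lands exactly on ``n_end`` and every size is rounded to the nearest
        integer, floored at 2.
        """
        d = int(self.duration)
        if self.shape == "constant":
            return np.full(d, self.n_end, dtype=np.int64)
        ratio = (self.n_end / self.n_start) ** (1.0 / d)
        out = np.array(
            [max(2, round(self.n_start * ratio**t)) for t in range(1, d + 1)],
            dtype=np.int64,
        )
        out[-1] = self.n_end
        return out


@dataclass(frozen=True)
class DemographyModel:
    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("demography needs at least one epoch")

    @property
    def initial_size(self) -> int:
        return self.epochs[0].n_start

    def size_trajectory(self) -> np.ndarray:
        """Per-generation diploid size, initial generation first."""
        return np.concatenate(
            [[self.initial_size]] + [e.sizes() for e in self.epochs]
        )

    @property
    def total_generations(self) -> int:
        return int(sum(e.duration for e in self.epochs))


@dataclass(frozen=True)
class DFEModel:
    """Point mass at neutrality plus a gamma-distributed deleterious class.

    ``mean_s`` is the mean (negative) homozygous selection coefficient of
    the deleterious class; ``h`` the dominance of the derived allele.
    """

    p_neutral: float = 0.3
    gamma_shape: float = 0.186
    mean_s: float = -0.01
    h: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_neutral <= 1.0:
            raise ValueError("p_neutral must lie in [0, 1]")
        if self.mean_s > 0:
            raise ValueError("mean_s must be <= 0 (deleterious class)")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must lie in [0, 1]")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")

    @property
    def gamma_scale(self) -> float:
        return abs(self.mean_s) / self.gamma_shape


def neutral_dfe() -> DFEModel:
    return DFEModel(p_neutral=1.0)


@dataclass(frozen=True)
class GenomeModel:
    n_genes: int = 25_314
    gene_length: int = 1_000
    n_chromosomes: int = 21
    mu: float = 1.12e-8  # mutations / bp / generation

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.gene_length < 1 or self.n_chromosomes < 1:
            raise ValueError("genome dimensions must be positive")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")

    @property
    def total_length(self) -> int:
        return self.n_genes * self.gene_length

    def chrom_of_gene(self, gene: np.ndarray) -> np.ndarray:
        """Genes assigned to chromosomes proportionally (contiguous blocks)."""
        return (np.asarray(gene, dtype=np.int64) * self.n_chromosomes) // self.n_genes

    def chrom_start_gene(self) -> np.ndarray:
        genes = np.arange(self.n_genes, dtype=np.int64)
        chroms = self.chrom_of_gene(genes)
        return np.searchsorted(chroms, np.arange(self.n_chromosomes))

    def chrom_lengths(self) -> np.ndarray:
        starts = self.chrom_start_gene()
        ends = np.append(starts[1:], self.n_genes)
        return (ends - starts) * self.gene_length


def bottleneck_demography() -> DemographyModel:
    """The whaling-era demographic model of the Southern Ocean study system:
    long constant burn-in at N=16,000, exponential crash to N=375 over five
    generations, exponential recovery to N=8,000 over ten."""
    return DemographyModel(
        epochs=(
            Epoch(500_000, 16_000, 16_000, "constant"),
            Epoch(5, 16_000, 375, "exponential"),
            Epoch(10, 375, 8_000, "exponential"),
        )
    )


@dataclass(frozen=True)
class RescaledModel:
    """A demography/DFE/genome triple plus a per-epoch scaling factor.

    ``epoch_scale[e]`` multiplies the mutation rate and the selection
    coefficients while the epoch's population size (already stored scaled
    in ``demography``) is divided by the same factor.
    """

    demography: DemographyModel
    dfe: DFEModel
    genome: GenomeModel
    epoch_scale: tuple[float, ...]

    @property
    def mu_burnin(self) -> float:
        return self.genome.mu * self.epoch_scale[0]

    @property
    def mean_s_burnin(self) -> float:
        return self.dfe.mean_s * self.epoch_scale[0]


def rescale_model(
    demography: DemographyModel,
    dfe: DFEModel,
    genome: GenomeModel,
    lam: float,
    scale_bottleneck: bool = False,
) -> RescaledModel:
    """Population-size rescaling to desk scale.

    The burn-in (first) epoch is shrunk: size and duration divided by
    ``lam``, with mutation rate and selection coefficients multiplied by
    ``lam`` inside it, which preserves 4*N*mu and 2*N*s.  Later epochs keep
    their natural generation counts; their sizes are divided by ``lam``
    only when ``scale_bottleneck`` is set (this amplifies per-generation
    drift and is off by default).
    """
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    burn = demography.epochs[0]
    new_dur = int(round(burn.duration / lam))
    if new_dur < 100:
        raise ValueError("rescaled burn-in would be shorter than 100 generations")

    def scaled_n(n: int) -> int:
        m = int(round(n / lam))
        if m < 2:
            raise ValueError(f"rescaling N={n} by lambda={lam} yields N < 2")
        return m

    epochs = [replace(burn, duration=new_dur, n_start=scaled_n(burn.n_start),
                      n_end=scaled_n(burn.n_end))]
    scales = [float(lam)]
    for e in demography.epochs[1:]:
        if scale_bottleneck:
            epochs.append(replace(e, n_start=scaled_n(e.n_start), n_end=scaled_n(e.n_end)))
            scales.append(float(lam))
        else:
            epochs.append(e)
            scales.append(1.0)
    return RescaledModel(
        demography=DemographyModel(tuple(epochs)),
        dfe=dfe,
        genome=genome,
        epoch_scale=tuple(scales),
    )


# ---------------------------------------------------------------------------
# impact categories
# ---------------------------------------------------------------------------

def assign_impact_categories(
    s_values: np.ndarray,
    thresholds: tuple[float, float] = (1e-4, 1e-2),
    neutral_low_fraction: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Label sites HIGH/MODERATE/LOW/MODIFIER from |s|.

    Neutral sites (s == 0) split between MODIFIER and LOW (the LOW share is
    ``neutral_low_fraction``, seeded); deleterious sites bin by |s| at the
    two thresholds.
    """
    t1, t2 = thresholds
    if not 0 < t1 < t2:
        raise ValueError("impact thresholds must satisfy 0 < t1 < t2")
    s = np.abs(np.asarray(s_values, dtype=float))
    out = np.empty(s.shape, dtype=object)
    rng = np.random.default_rng(seed)
    neutral = s == 0
    low_draw = rng.random(s.shape) < neutral_low_fraction
    out[neutral & low_draw] = "LOW"
    out[neutral & ~low_draw] = "MODIFIER"
    out[~neutral & (s <= t1)] = "LOW"
    out[~neutral & (s > t1) & (s <= t2)] = "MODERATE"
    out[~neutral & (s > t2)] = "HIGH"
    return out


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

@dataclass
class CohortSample:
    """12 (or so) diploids drawn from one timepoint, aligned to the shared
    replicate site table."""

    label: str
    matrix: GenotypeMatrix
    generation: int  # absolute generation index (0 = initial)


@dataclass
class SimulationReplicate:
    seed: int
    sites: pd.DataFrame
    cohorts: dict[str, CohortSample]
    summaries: dict
    genome: GenomeModel
    dfe: DFEModel

    def recompute_summaries(self) -> dict:
        """Recompute the stored summaries from the stored genotypes."""
        order = self.summaries.get("timepoint_order", list(self.cohorts))
        return _summarize(self.cohorts, self.sites, self.genome, self.dfe, order)


def _filter_structure(data, ptr, keep, remap, id_bits):
    """Remap one CSR mutation-carrier structure after table compaction.

    Haplotype entries are composite ``(gene << id_bits) | id``: the id half
    is remapped, the gene half preserved.
    """
    n_haps = len(ptr) - 1
    mask = data.dtype.type((1 << id_bits) - 1)
    ids = data & mask
    elem_keep = keep[ids]
    hap_of = np.repeat(np.arange(n_haps), np.diff(ptr))
    kept_per_hap = np.bincount(hap_of[elem_keep], minlength=n_haps)
    new_ptr = np.concatenate([[0], np.cumsum(kept_per_hap)]).astype(np.int64)
    new_data = (data[elem_keep] & ~mask) | remap[ids[elem_keep]].astype(data.dtype)
    return new_data, new_ptr


def _prune(state: dict) -> int:
    """Drop fixed and lost mutations, compact the table, remap ids.

    Returns the number of mutations that had fixed.
    """
    n_mut = state["n_mut"]
    id_bits = state["id_bits"]
    mask = (1 << id_bits) - 1
    n_haps = len(state["neu_ptr"]) - 1
    counts = np.bincount(
        state["neu_data"] & mask, minlength=n_mut
    ) + np.bincount(state["sel_data"] & mask, minlength=n_mut)
    keep = (counts > 0) & (counts < n_haps)
    n_fixed = int((counts == n_haps).sum())
    remap = (np.cumsum(keep) - 1).astype(np.int64)
    state["neu_data"], state["neu_ptr"] = _filter_structure(
        state["neu_data"], state["neu_ptr"], keep, remap, id_bits
    )
    state["sel_data"], state["sel_ptr"] = _filter_structure(
        state["sel_data"], state["sel_ptr"], keep, remap, id_bits
    )
    for name in ("mut_pos", "mut_s", "mut_gene", "lw_het", "lw_hom"):
        state[name] = state[name][:n_mut][keep].copy()
    state["n_mut"] = int(keep.sum())
    return n_fixed


def _repack_to_int64(state: dict) -> None:
    """Widen packed int32 composites to the int64 layout (id_bits = 32)."""
    old_bits = state["id_bits"]
    old_mask = (1 << old_bits) - 1
    for name in ("neu_data", "sel_data"):
        data = state[name].astype(np.int64)
        ids = data & old_mask
        genes = data >> old_bits
        state[name] = (genes << 32) | ids
    state["id_bits"] = 32


def _grow(arr: np.ndarray, need: int) -> np.ndarray:
    if arr.shape[0] >= need:
        return arr
    new = np.empty(max(need, 2 * arr.shape[0] + 1024), dtype=arr.dtype)
    new[: arr.shape[0]] = arr
    return new


def simulate_replicate(
    demography: DemographyModel,
    dfe: DFEModel,
    genome: GenomeModel,
    sample_size: int = 12,
    timepoints: Mapping[str, int] | None = None,
    seed: int = 0,
    epoch_scale: Sequence[float] | None = None,
    prune_interval: int = 100,
    ti_fraction: float = 2.0 / 3.0,
) -> SimulationReplicate:
    """Run one forward replicate and sample cohorts.

    ``timepoints`` maps a cohort label to an epoch index; the cohort is
    drawn without replacement at the final generation of that epoch.  The
    default, for multi-epoch models, samples ``pre_bottleneck`` at the end
    of the first epoch and ``post_recovery`` at the end of the last; for a
    single-epoch model a single ``final`` cohort is drawn.

    Pass ``rescale_model(...)`` output via :func:`simulate_rescaled` or
    supply ``epoch_scale`` directly (one factor per epoch, default all 1).
    """
    n_epochs = len(demography.epochs)
    if timepoints is None:
        if n_epochs == 1:
            timepoints = {"final": 0}
        else:
            timepoints = {"pre_bottleneck": 0, "post_recovery": n_epochs - 1}
    if not timepoints:
        raise ValueError("at least one timepoint is required")
    for label, e in timepoints.items():
        if not 0 <= e < n_epochs:
            raise ValueError(f"timepoint {label!r} refers to epoch {e} of {n_epochs}")
    if epoch_scale is None:
        epoch_scale = (1.0,) * n_epochs
    if len(epoch_scale) != n_epochs:
        raise ValueError("epoch_scale must have one factor per epoch")

    # sampled populations must be large enough
    for label, e in timepoints.items():
        n_at = int(demography.epochs[e].sizes()[-1])
        if sample_size > n_at:
            raise ValueError(
                f"sample_size {sample_size} exceeds population size {n_at} "
                f"at timepoint {label!r}"
            )

    ss = np.random.SeedSequence(seed)
    ss_chunks, ss_sample, ss_emit = ss.spawn(3)
    rng_chunks = np.random.default_rng(ss_chunks)
    rng_sample = np.random.default_rng(ss_sample)
    rng_emit = np.random.default_rng(ss_emit)

    L = genome.total_length
    gene_len = genome.gene_length

    # population state: one mutation table, two carrier structures; packed
    # int32 composites while ids fit, widened to int64 on demand
    n0 = demography.initial_size
    cap = 1 << 14
    gene_bits = max(1, int(np.ceil(np.log2(max(2, genome.n_genes)))))
    id_bits = 31 - gene_bits
    entry_dtype = np.int32 if id_bits >= 16 else np.int64
    if entry_dtype is np.int64:
        id_bits = 32
    state = {
        "id_bits": id_bits,
        "neu_data": np.empty(0, dtype=entry_dtype),
        "neu_ptr": np.zeros(2 * n0 + 1, dtype=np.int64),
        "sel_data": np.empty(0, dtype=entry_dtype),
        "sel_ptr": np.zeros(2 * n0 + 1, dtype=np.int64),
        "mut_pos": np.empty(cap, dtype=np.int64),
        "mut_s": np.empty(cap, dtype=np.float64),
        "mut_gene": np.empty(cap, dtype=np.int32),
        "lw_het": np.empty(cap, dtype=np.float64),
        "lw_hom": np.empty(cap, dtype=np.float64),
        "n_mut": 0,
    }
    total_fixed = 0

    sampled: dict[str, tuple[list, int]] = {}
    ids_frozen = False  # once a cohort is drawn, mutation ids must not move
    gen_abs = 0

    epoch_end_labels: dict[int, list[str]] = {}
    for label, e in timepoints.items():
        epoch_end_labels.setdefault(e, []).append(label)

    prev_lam = None
    for e_idx, epoch in enumerate(demography.epochs):
        lam = float(epoch_scale[e_idx])
        if prev_lam is not None and lam != prev_lam:
            # the effective selection strength changed: refresh log terms
            _wf.refresh_log_terms(
                state["mut_s"], state["lw_het"], state["lw_hom"],
                state["n_mut"], lam, dfe.h,
            )
        prev_lam = lam
        mu_per_gamete = genome.mu * lam * L
        sizes = epoch.sizes()
        done = 0
        while done < len(sizes):
            chunk = sizes[done : done + prune_interval]
            max_n = int(chunk.max())
            expected = 2.0 * max_n * mu_per_gamete * len(chunk)
            need = state["n_mut"] + int(1.6 * expected) + 4096
            if need > (1 << state["id_bits"]):
                _repack_to_int64(state)
            for name in ("mut_pos", "mut_s", "mut_gene", "lw_het", "lw_hom"):
                state[name] = _grow(state[name], need)
            stamp = np.zeros(state["mut_pos"].shape[0], dtype=np.int64)
            chunk_seed = int(rng_chunks.integers(0, 2**31 - 1))
            (
                state["neu_data"], state["neu_ptr"],
                state["sel_data"], state["sel_ptr"],
                state["n_mut"],
            ) = _wf._run_generations(
                state["neu_data"], state["neu_ptr"],
                state["sel_data"], state["sel_ptr"],
                chunk.astype(np.int64),
                state["mut_pos"], state["mut_s"], state["mut_gene"],
                state["lw_het"], state["lw_hom"], stamp,
                state["n_mut"],
                mu_per_gamete,
                lam,
                dfe.h,
                dfe.p_neutral,
                dfe.gamma_shape,
                dfe.gamma_scale,
                np.int64(L),
                np.int64(gene_len),
                np.int64(genome.n_genes),
                np.int64(state["id_bits"]),
                chunk_seed,
            )
            done += len(chunk)
            gen_abs += len(chunk)
            if not ids_frozen:
                total_fixed += _prune(state)
        for label in epoch_end_labels.get(e_idx, []):
            neu_ptr, sel_ptr = state["neu_ptr"], state["sel_ptr"]
            neu_data, sel_data = state["neu_data"], state["sel_data"]
            n_cur = (len(neu_ptr) - 1) // 2
            chosen = rng_sample.choice(n_cur, size=sample_size, replace=False)
            chosen.sort()
            mask = (1 << state["id_bits"]) - 1
            haps = []
            for i in chosen:
                for j in (2 * i, 2 * i + 1):
                    comp = np.concatenate(
                        [
                            neu_data[neu_ptr[j] : neu_ptr[j + 1]].astype(np.int64),
                            sel_data[sel_ptr[j] : sel_ptr[j + 1]].astype(np.int64),
                        ]
                    )
                    haps.append(comp & mask)
            sampled[label] = (haps, gen_abs)
            ids_frozen = True

    # order cohort labels by sampling epoch (time-forward)
    order = sorted(timepoints, key=lambda k: (timepoints[k], k))
    n_mut = state["n_mut"]
    cohorts, sites = _emit(
        sampled, order,
        state["mut_pos"][:n_mut], state["mut_s"][:n_mut], state["mut_gene"][:n_mut],
        genome, dfe, ti_fraction, rng_emit,
    )
    summaries = _summarize(cohorts, sites, genome, dfe, order)
    summaries["generations_run"] = gen_abs
    summaries["fixed_during_run"] = total_fixed
    return SimulationReplicate(
        seed=seed, sites=sites, cohorts=cohorts, summaries=summaries,
        genome=genome, dfe=dfe,
    )


def simulate_rescaled(model: RescaledModel, **kwargs) -> SimulationReplicate:
    """Convenience wrapper: run :func:`simulate_replicate` on a rescaled model."""
    return simulate_replicate(
        model.demography, model.dfe, model.genome,
        epoch_scale=model.epoch_scale, **kwargs,
    )


def _emit(sampled, order, mut_pos, mut_s, mut_gene, genome, dfe, ti_fraction, rng):
    """Materialize cohort genotype matrices over the union of segregating
    sites, drop sites fixed across the combined cohorts, and build the
    shared site table (ref = ancestral by construction)."""
    all_haps = [h for label in order for h in sampled[label][0]]
    n_haps_total = len(all_haps)
    if all_haps and any(len(h) for h in all_haps):
        concat = np.concatenate([h for h in all_haps if len(h)])
    else:
        concat = np.empty(0, dtype=np.int64)
    ids, counts = np.unique(concat, return_counts=True)
    ids = ids[(counts > 0) & (counts < n_haps_total)]

    # one biallelic SNP per position: on (rare) positional collisions keep
    # the oldest mutation
    pos = mut_pos[ids]
    df_ord = np.lexsort((ids, pos))
    ids, pos = ids[df_ord], pos[df_ord]
    keep = np.ones(len(ids), dtype=bool)
    keep[1:] = pos[1:] != pos[:-1]
    ids, pos = ids[keep], pos[keep]

    gene = mut_gene[ids]
    s_vals = mut_s[ids]
    chrom_idx = genome.chrom_of_gene(gene)
    chrom_start = genome.chrom_start_gene()
    pos_in_chrom = pos - chrom_start[chrom_idx] * genome.gene_length + 1
    chrom_names = np.array([f"chr{c + 1}" for c in range(genome.n_chromosomes)])

    n_sites = len(ids)
    ref = rng.choice(_BASES, size=n_sites)
    is_ti = rng.random(n_sites) < ti_fraction
    alt = np.empty(n_sites, dtype=object)
    tv_pick = rng.integers(0, 2, size=n_sites)
    for i in range(n_sites):
        r = ref[i]
        alt[i] = (
            _TRANSITION_PARTNER[r] if is_ti[i] else _TRANSVERSION_PARTNERS[r][tv_pick[i]]
        )
    impact = assign_impact_categories(
        s_vals, seed=int(rng.integers(0, 2**31 - 1))
    )

    sites = make_site_table(
        chrom=chrom_names[chrom_idx],
        pos=pos_in_chrom,
        ref=ref,
        alt=alt,
        impact=impact,
        s=s_vals,
        gene=gene,
        ancestral=ref.copy(),
    )
    # site tables are sorted by genome coordinate
    site_order = np.lexsort((sites["pos"].to_numpy(), chrom_idx))
    sites = sites.iloc[site_order].reset_index(drop=True)
    ids_by_coord = ids[site_order]

    # genotype matrices: count derived copies per individual per site
    id_sorted = np.sort(ids)
    coord_of_id = np.empty(len(ids), dtype=np.int64)
    coord_of_id[np.searchsorted(id_sorted, ids_by_coord)] = np.arange(len(ids))

    cohorts: dict[str, CohortSample] = {}
    for label in order:
        haps, gen_at = sampled[label]
        n_ind = len(haps) // 2
        gt = np.zeros((n_ind, len(ids)), dtype=np.int8)
        for i in range(n_ind):
            for hap in (haps[2 * i], haps[2 * i + 1]):
                if len(hap) == 0:
                    continue
                loc = np.searchsorted(id_sorted, hap)
                ok = (loc < len(ids)) & (id_sorted[np.minimum(loc, len(ids) - 1)] == hap)
                gt[i, coord_of_id[loc[ok]]] += 1
        prefix = {"pre_bottleneck": "HIS", "post_recovery": "CON"}.get(
            label, label[:3].upper()
        )
        names = [f"{prefix}_{i + 1:02d}" for i in range(n_ind)]
        cohorts[label] = CohortSample(
            label=label,
            matrix=GenotypeMatrix(samples=names, gt=gt),
            generation=gen_at,
        )
    return cohorts, sites


def _hom_runs(gt_row: np.ndarray, pos: np.ndarray, min_sites: int) -> tuple[int, int]:
    """(total bp in homozygous runs of >= min_sites called sites, longest run bp).

    Missing genotypes are skipped; a heterozygote breaks the run.
    """
    called = gt_row != MISSING
    g = gt_row[called]
    p = pos[called]
    total = 0
    longest = 0
    start = None
    count = 0
    for k in range(len(g) + 1):
        hom = k < len(g) and g[k] != HET
        if hom:
            if start is None:
                start = k
                count = 0
            count += 1
        else:
            if start is not None:
                length = int(p[k - 1] - p[start] + 1)
                longest = max(longest, length)
                if count >= min_sites:
                    total += length
                start = None
    return total, longest


def _fitness_from_genotypes(gt: np.ndarray, s: np.ndarray, h: float) -> np.ndarray:
    """Relative fitness over the emitted (segregating) sites."""
    se = np.clip(s, -1.0, 0.0)
    sel = se != 0.0
    if not sel.any():
        return np.ones(gt.shape[0])
    g = gt[:, sel].astype(np.float64)
    se = se[sel]
    log_het = np.log1p(h * se)
    with np.errstate(divide="ignore"):
        log_hom = np.where(se <= -1.0, -np.inf, np.log1p(se))
    logw = (g == 1) @ log_het + (g == 2) @ log_hom
    return np.exp(logw)


def _summarize(cohorts, sites, genome, dfe, order) -> dict:
    L = genome.total_length
    s_vals = sites["s"].to_numpy() if "s" in sites else np.zeros(len(sites))
    impact = sites["impact"].to_numpy() if len(sites) else np.empty(0, dtype=object)
    pos = sites["pos"].to_numpy() if len(sites) else np.empty(0, dtype=np.int64)
    chrom = sites["chrom"].to_numpy() if len(sites) else np.empty(0, dtype=object)
    chrom_slices = []
    if len(sites):
        # sites are coordinate-sorted; runs never span chromosomes
        change = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
        bounds = np.concatenate([[0], change, [len(sites)]])
        chrom_slices = [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]

    out: dict = {"timepoint_order": list(order), "cohorts": {}}
    for label in order:
        m = cohorts[label].matrix
        het_per_ind = (m.gt == HET).sum(axis=1) / L
        derived_counts = {}
        any_derived = (m.gt > 0).any(axis=0)
        for cat in IMPACT_LEVELS:
            derived_counts[cat] = int((any_derived & (impact == cat)).sum())
        totals = []
        longests = []
        for i in range(m.n_samples):
            tot = 0
            lng = 0
            for sl in chrom_slices:
                t, g = _hom_runs(m.gt[i, sl], pos[sl], min_sites=25)
                tot += t
                lng = max(lng, g)
            totals.append(tot)
            longests.append(lng)
        out["cohorts"][label] = {
            "mean_het": float(het_per_ind.mean()),
            "het_per_individual": [float(x) for x in het_per_ind],
            "segregating_sites": int((m.gt > 0).any(axis=0).sum()),
            "derived_counts_by_impact": derived_counts,
            "mean_fitness": float(_fitness_from_genotypes(m.gt, s_vals, dfe.h).mean()),
            "hom_run_total_bp_mean": float(np.mean(totals)) if totals else 0.0,
            "longest_hom_run_bp_mean": float(np.mean(longests)) if longests else 0.0,
        }
    if len(order) >= 2:
        first = out["cohorts"][order[0]]["mean_het"]
        last = out["cohorts"][order[-1]]["mean_het"]
        out["het_loss_pct"] = (
            float("nan") if first == 0 else 100.0 * (1.0 - last / first)
        )
    return out


# ---------------------------------------------------------------------------
# the simulation study (paper-style bottleneck experiment at desk scale)
# ---------------------------------------------------------------------------

def run_simulation_study(
    n_replicates: int = 20,
    n_genes: int = 500,
    lam: float = 20.0,
    seed: int = 1,
    sample_size: int = 12,
    dfe: DFEModel | None = None,
    scale_bottleneck: bool = False,
) -> pd.DataFrame:
    """Replicated bottleneck experiment: rescaled burn-in, natural-generation
    crash and recovery, ``sample_size`` diploids per timepoint.

    Returns one row per replicate with pre/post heterozygosity and the
    percent heterozygosity loss.
    """
    dfe = dfe or DFEModel()
    genome = GenomeModel(n_genes=n_genes)
    model = rescale_model(
        bottleneck_demography(), dfe, genome, lam, scale_bottleneck=scale_bottleneck
    )
    rep_seeds = (
        np.random.SeedSequence(seed).generate_state(n_replicates, dtype=np.uint64)
        % (2**31 - 1)
    ).astype(np.int64)
    rows = []
    for r, s in enumerate(rep_seeds):
        rep = simulate_rescaled(model, sample_size=sample_size, seed=int(s))
        summ = rep.summaries
        rows.append(
            {
                "replicate": r,
                "seed": int(s),
                "het_pre": summ["cohorts"]["pre_bottleneck"]["mean_het"],
                "het_post": summ["cohorts"]["post_recovery"]["mean_het"],
                "loss_pct": summ["het_loss_pct"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# read-depth fields and deamination-style artifacts
# ---------------------------------------------------------------------------

def attach_read_depths(
    matrix: GenotypeMatrix,
    target_depth: float = 6.0,
    seed: int = 0,
    gq_per_depth: float = 4.0,
) -> GenotypeMatrix:
    """Draw per-genotype DP ~ Poisson(target_depth), allelic depths
    (Binomial(DP, 1/2) alternate reads for heterozygotes) and a GQ that
    grows with depth.  Missing genotypes carry -1 everywhere."""
    rng = np.random.default_rng(seed)
    gt = matrix.gt
    dp = rng.poisson(target_depth, size=gt.shape).astype(np.int32)
    alt = np.zeros_like(dp)
    het = gt == HET
    alt[het] = rng.binomial(dp[het], 0.5)
    alt[gt == HOM_ALT] = dp[gt == HOM_ALT]
    ref = dp - alt
    gq = np.minimum(99, rng.poisson(gq_per_depth * dp)).astype(np.int32)
    miss = gt == MISSING
    for arr in (dp, alt, ref, gq):
        arr[miss] = -1
    return GenotypeMatrix(
        samples=list(matrix.samples), gt=gt.copy(), dp=dp, gq=gq,
        ad_ref=ref, ad_alt=alt,
    )


def add_historical_artifacts(
    matrix: GenotypeMatrix,
    sites: pd.DataFrame,
    deamination_rate: float,
    target_depth: float = 6.0,
    seed: int = 0,
    carrier_samples: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Emulate a low-coverage historical cohort: attach read depths and
    inject spurious C>T / G>A transition sites carried by 1-2 derived
    copies, the signature of post-mortem cytosine deamination.

    ``carrier_samples`` restricts which samples can carry an artifact (by
    default all samples in the matrix; pass the historical subset when the
    matrix mixes cohorts).  The returned site table carries an
    ``is_artifact`` ground-truth column (internal; the VCF writer does not
    emit it).
    """
    if not 0.0 <= deamination_rate < 1.0:
        raise ValueError("deamination_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = attach_read_depths(
        matrix, target_depth, seed=int(rng.integers(0, 2**31 - 1))
    )
    if carrier_samples is None:
        carrier_rows = np.arange(out.n_samples)
    else:
        carrier_rows = np.array([out.samples.index(s) for s in carrier_samples])
        if len(carrier_rows) == 0:
            raise ValueError("carrier_samples must not be empty")
    sites = sites.copy()
    if "is_artifact" not in sites:
        sites["is_artifact"] = False
    n_inject = int(rng.binomial(len(sites), deamination_rate)) if len(sites) else 0
    if n_inject == 0:
        return out, sites

    taken = {(c, p) for c, p in zip(sites["chrom"], sites["pos"])}
    chrom_max = sites.groupby("chrom")["pos"].max().to_dict()
    chroms = list(chrom_max)
    new_rows = []
    gt_cols, dp_cols, gq_cols, adr_cols, ada_cols = [], [], [], [], []
    n = out.n_samples
    for _ in range(n_inject):
        while True:
            c = chroms[rng.integers(0, len(chroms))]
            p = int(rng.integers(1, chrom_max[c] + 1000))
            if (c, p) not in taken:
                taken.add((c, p))
                break
        ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
        copies = min(1 + int(rng.random() < 0.5), len(carrier_rows))
        carriers = rng.choice(carrier_rows, size=copies, replace=False)
        gt = np.zeros(n, dtype=np.int8)
        gt[carriers] = HET
        dp = rng.poisson(target_depth, size=n).astype(np.int32)
        ada = np.zeros(n, dtype=np.int32)
        ada[carriers] = np.minimum(dp[carriers], 1 + rng.poisson(0.3, size=copies))
        adr = dp - ada
        gq = np.minimum(99, rng.poisson(3.0 * dp)).astype(np.int32)
        new_rows.append(
            {
                "chrom": c, "pos": p, "ref": ref, "alt": alt,
                "is_transition": True, "impact": "MODIFIER", "is_artifact": True,
            }
        )
        gt_cols.append(gt)
        dp_cols.append(dp)
        gq_cols.append(gq)
        adr_cols.append(adr)
        ada_cols.append(ada)

    extra = pd.DataFrame(new_rows)
    for col in sites.columns:
        if col not in extra.columns:
            kind = sites[col].dtype.kind
            extra[col] = 0.0 if kind == "f" else 0 if kind in "iu" else None
    if "ancestral" in sites.columns:
        extra["ancestral"] = extra["ref"]
    sites2 = pd.concat([sites, extra[sites.columns]], ignore_index=True)

    def app(base, cols, fill):
        add = np.column_stack(cols) if cols else np.empty((n, 0), dtype=np.int32)
        if base is None:
            base = np.full(matrix.gt.shape, fill, dtype=np.int32)
        return np.hstack([base, add])

    merged = GenotypeMatrix(
        samples=list(out.samples),
        gt=np.hstack([out.gt, np.column_stack(gt_cols).astype(np.int8)]),
        dp=app(out.dp, dp_cols, -1),
        gq=app(out.gq, gq_cols, -1),
        ad_ref=app(out.ad_ref, adr_cols, -1),
        ad_alt=app(out.ad_alt, ada_cols, -1),
    )
    # restore genomic sort order
    order = np.lexsort((sites2["pos"].to_numpy(), sites2["chrom"].to_numpy()))
    sites2 = sites2.iloc[order].reset_index(drop=True)
    merged = merged.take_sites(order)
    return merged, sites2


def outgroup_alleles(
    sites: pd.DataFrame, divergence: float = 0.02, seed: int = 0
) -> pd.Series:
    """Outgroup allele per site: the true ancestral (reference) base except
    at a ``divergence`` fraction of sites where lineage-specific change has
    replaced it (drawn as the alternate allele, the worst case for
    polarization)."""
    rng = np.random.default_rng(seed)
    flip = rng.random(len(sites)) < divergence
    out = sites["ref"].to_numpy(dtype=object).copy()
    out[flip] = sites["alt"].to_numpy(dtype=object)[flip]
    return pd.Series(out, index=sites.index, name="outgroup")


def synthetic_cohort(
    n_sites: int,
    n_samples: int,
    seed: int = 0,
    ti_fraction: float = 2.0 / 3.0,
    n_chromosomes: int = 4,
    chrom_length: int = 1_000_000,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Direct (non-forward-simulated) cohort fixture.

    Alternate-allele frequencies follow a neutral site-frequency spectrum
    (mass proportional to 1/i over allele counts in a notional pool of 100
    chromosomes) and genotypes are Hardy-Weinberg draws - a quick way to
    build large, realistic matrices for filter and load testing without a
    Wright-Fisher run.  The reference allele plays the ancestral role.
    """
    rng = np.random.default_rng(seed)
    pool = 100
    weights = 1.0 / np.arange(1, pool)
    weights /= weights.sum()
    freqs = rng.choice(np.arange(1, pool), size=n_sites, p=weights) / pool
    gt = rng.binomial(1, freqs, size=(n_samples, n_sites)) + rng.binomial(
        1, freqs, size=(n_samples, n_sites)
    )
    chrom_idx = rng.integers(0, n_chromosomes, size=n_sites)
    pos = rng.choice(chrom_length, size=n_sites, replace=False)
    order = np.lexsort((pos, chrom_idx))
    chrom_idx, pos, freqs = chrom_idx[order], pos[order], freqs[order]
    gt = gt[:, order].astype(np.int8)

    ref = rng.choice(_BASES, size=n_sites)
    is_ti = rng.random(n_sites) < ti_fraction
    tv_pick = rng.integers(0, 2, size=n_sites)
    alt = np.array(
        [
            _TRANSITION_PARTNER[r] if t else _TRANSVERSION_PARTNERS[r][k]
            for r, t, k in zip(ref, is_ti, tv_pick)
        ],
        dtype=object,
    )
    sites = make_site_table(
        chrom=np.array([f"chr{c + 1}" for c in chrom_idx]),
        pos=pos + 1,
        ref=ref,
        alt=alt,
        impact=np.full(n_sites, "MODIFIER", dtype=object),
        ancestral=ref.copy(),
        true_freq=freqs,
    )
    matrix = GenotypeMatrix(
        samples=[f"S_{i + 1:02d}" for i in range(n_samples)], gt=gt
    )
    return matrix, sites


# ---------------------------------------------------------------------------
# catch series and synthetic estimator output
# ---------------------------------------------------------------------------

def generate_catch_series(
    nc_trajectory: Sequence[float],
    reporting_noise: float = 0.0,
    seed: int = 0,
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-interval removals implied by a census-size trajectory.

    ``nc_trajectory`` is ordered forward in time; the catch in interval t
    is ``max(0, -(Nc_t - Nc_{t-1})) * (1 + noise)``, i.e. reported removals
    explain population declines up to multiplicative reporting noise.
    Cumulative catches are non-decreasing by construction.
    """
    nc = np.asarray(nc_trajectory, dtype=float)
    if (nc < 0).any():
        raise ValueError("census trajectory must be non-negative")
    rng = np.random.default_rng(seed)
    drops = np.maximum(0.0, -np.diff(nc))
    noise = rng.normal(0.0, reporting_noise, size=drops.shape) if reporting_noise else 0.0
    catches = np.maximum(0.0, drops * (1.0 + noise))
    if years is None:
        years = np.arange(1, len(nc))
    else:
        years = np.asarray(years)
        if len(years) != len(catches):
            raise ValueError("need one year per interval (len(nc) - 1)")
    return pd.DataFrame(
        {"year": years, "catches": catches, "cumulative": np.cumsum(catches)}
    )


def synthetic_ne_runs(
    ne_per_generation: Sequence[float],
    n_runs: int = 40,
    cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate the per-run output of an LD-based Ne estimator: one column
    per independent run, multiplicative lognormal noise around the true
    trajectory, indexed by generations before sampling (1 = parents)."""
    ne = np.asarray(ne_per_generation, dtype=float)
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0
    cols = {"generation": np.arange(1, len(ne) + 1)}
    for r in range(n_runs):
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=len(ne)) if sigma else 1.0
        cols[f"run_{r + 1}"] = ne * noise
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# plain-text config round-trip
# ---------------------------------------------------------------------------

def models_to_dict(
    demography: DemographyModel, dfe: DFEModel, genome: GenomeModel
) -> dict:
    return {
        "demography": [
            {"duration": e.duration, "n_start": e.n_start, "n_end": e.n_end,
             "shape": e.shape}
            for e in demography.epochs
        ],
        "dfe": {
            "p_neutral": dfe.p_neutral, "gamma_shape": dfe.gamma_shape,
            "mean_s": dfe.mean_s, "h": dfe.h,
        },
        "genome": {
            "n_genes": genome.n_genes, "gene_length": genome.gene_length,
            "n_chromosomes": genome.n_chromosomes, "mu": genome.mu,
        },
    }


def models_from_dict(d: Mapping) -> tuple[DemographyModel, DFEModel, GenomeModel]:
    demography = DemographyModel(tuple(Epoch(**e) for e in d["demography"]))
    return demography, DFEModel(**d["dfe"]), GenomeModel(**d["genome"])
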