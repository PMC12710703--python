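"""Genome-wide heterozygosity, HMM-based runs of homozygosity (ROH), and
the inbreeding coefficient F_ROH.

The ROH caller is a two-state hidden Markov model over the ordered,
non-missing genotypes of one sample on one chromosome:

* state AZ (autozygous): heterozygous calls appear only through genotyping
  error, ``P(het | AZ) = error_rate``;
* state HW (non-autozygous): heterozygosity follows Hardy-Weinberg
  expectation at the site's alternate-allele frequency,
  ``P(het | HW) = 2 p (1 - p)``.

Transition probabilities between adjacent sites a physical distance ``d``
apart derive from per-bp switch rates, ``P(switch) = 1 - exp(-rate * d)``.
The decoder is exact Viterbi; ties prefer the non-autozygous state so
that autozygosity is never over-called.  Contiguous AZ stretches are
reported as segments bounded by their outermost homozygous sites and kept
only when they contain at least ``min_hom_sites`` homozygous genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, HET, MISSING


@dataclass(frozen=True)
class RohConfig:
    """ROH HMM parameters.

    The switch rates follow the published defaults of the widely used
    HMM-based caller for unphased genotypes (entry into autozygosity
    6.7e-8 per bp, exit 5e-9 per bp, genotyping-error emission 1e-4);
    they are package defaults, overridable per dataset.
    """

    az_entry_rate: float = 6.7e-8   # per bp, HW -> AZ
    az_exit_rate: float = 5e-9      # per bp, AZ -> HW
    error_rate: float = 1e-4        # P(het | autozygous)
    min_hom_sites: int = 50
    min_segment_length: float = 1e6  # F_ROH length threshold (bp)
    genome_length: float = 2.2e9     # autosomal genome length (bp)

    def __post_init__(self) -> None:
        for name in ("az_entry_rate", "az_exit_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.min_hom_sites < 1 or self.min_segment_length <= 0:
            raise ValueError("ROH thresholds must be positive")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")


@dataclass(frozen=True)
class ROHSegment:
    """One run of homozygosity: 1-based inclusive coordinates."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_sites: int  # homozygous genotypes inside the run

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must not exceed end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def genome_wide_heterozygosity(genotypes: np.ndarray, callable_sites: int) -> float:
    """Heterozygous genotypes over callable sites for one sample.

    ``callable_sites`` must count every position where the genome is
    callable, including monomorphic ones; with variant-only input it must
    be supplied externally (e.g. the generator's genome length).
    """
    if callable_sites <= 0:
        raise ValueError("callable_sites must be positive")
    g = np.asarray(genotypes)
    n_called = int((g != MISSING).sum())
    if n_called > callable_sites:
        raise ValueError(
            f"{n_called} genotyped sites exceed callable_sites={callable_sites}"
        )
    return float((g == HET).sum()) / float(callable_sites)


# ---------------------------------------------------------------------------
# the two-state HMM
# ---------------------------------------------------------------------------

_HW, _AZ = 0, 1  # decoder state codes; ties prefer HW


def _viterbi_path(
    obs_het: np.ndarray, p_alt: np.ndarray, dist: np.ndarray, config: RohConfig
) -> np.ndarray:
    """Exact Viterbi decoding; returns state per site (0 = HW, 1 = AZ).

    ``dist[k]`` is the bp distance between site ``k-1`` and ``k``
    (``dist[0]`` is ignored); uniform initial state probabilities.
    """
    n = len(obs_het)
    p = np.clip(p_alt, 1e-9, 1 - 1e-9)
    p_het_hw = np.clip(2 * p * (1 - p), 1e-12, 1.0)
    e = config.error_rate
    log_emit = np.empty((n, 2))
    log_emit[:, _HW] = np.where(obs_het, np.log(p_het_hw), np.log1p(-p_het_hw))
    log_emit[:, _AZ] = np.where(obs_het, np.log(e), np.log1p(-e))

    with np.errstate(divide="ignore"):
        p_enter = -np.expm1(-config.az_entry_rate * dist)  # HW -> AZ
        p_exit = -np.expm1(-config.az_exit_rate * dist)    # AZ -> HW
        log_enter = np.log(np.clip(p_enter, 1e-300, 1.0))
        log_stay_hw = np.log1p(-np.clip(p_enter, 0.0, 1 - 1e-15))
        log_exit = np.log(np.clip(p_exit, 1e-300, 1.0))
        log_stay_az = np.log1p(-np.clip(p_exit, 0.0, 1 - 1e-15))

    score = np.array([np.log(0.5), np.log(0.5)]) + log_emit[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for k in range(1, n):
        # into HW: stay from HW vs exit from AZ; ties keep HW provenance
        from_hw = score[_HW] + log_stay_hw[k]
        from_az = score[_AZ] + log_exit[k]
        if from_az > from_hw:
            new_hw, back[k, _HW] = from_az, _AZ
        else:
            new_hw, back[k, _HW] = from_hw, _HW
        # into AZ
        from_hw = score[_HW] + log_enter[k]
        from_az = score[_AZ] + log_stay_az[k]
        if from_hw >= from_az:
            new_az, back[k, _AZ] = from_hw, _HW
        else:
            new_az, back[k, _AZ] = from_az, _AZ
        score = np.array([new_hw, new_az]) + log_emit[k]

    states = np.empty(n, dtype=np.int8)
    states[-1] = _AZ if score[_AZ] > score[_HW] else _HW
    for k in range(n - 1, 0, -1):
        states[k - 1] = back[k, states[k]]
    return states


def _segments_from_states(
    states: np.ndarray,
    obs_het: np.ndarray,
    pos: np.ndarray,
    sample_id: str,
    chrom: str,
    min_hom_sites: int,
) -> list[ROHSegment]:
    segments = []
    n = len(states)
    k = 0
    while k < n:
        if states[k] != _AZ:
            k += 1
            continue
        j = k
        while j + 1 < n and states[j + 1] == _AZ:
            j += 1
        hom_idx = np.flatnonzero(~obs_het[k : j + 1]) + k
        if len(hom_idx) >= min_hom_sites:
            segments.append(
                ROHSegment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=int(pos[hom_idx[0]]),
                    end=int(pos[hom_idx[-1]]),
                    n_sites=len(hom_idx),
                )
            )
        k = j + 1
    return segments


def call_roh(
    matrix: GenotypeMatrix,
    sites: pd.DataFrame,
    allele_freqs: np.ndarray | None = None,
    config: RohConfig | None = None,
) -> list[ROHSegment]:
    """Call ROH segments for every sample, per chromosome.

    Alternate-allele frequencies default to being estimated from the
    dataset itself (called gene copies only); supply ``allele_freqs`` to
    use external estimates.
    """
    config = config or RohConfig()
    if matrix.n_sites != len(sites):
        raise ValueError("matrix and site table are misaligned")
    if allele_freqs is None:
        counts = matrix.alt_allele_counts().astype(float)
        called = matrix.called_allele_counts().astype(float)
        with np.errstate(invalid="ignore"):
            allele_freqs = np.where(called > 0, counts / np.maximum(called, 1), 0.0)
    allele_freqs = np.asarray(allele_freqs, dtype=float)

    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy(dtype=np.int64)
    segments: list[ROHSegment] = []
    for chrom in pd.unique(chrom_arr):
        on = np.flatnonzero(chrom_arr == chrom)
        for i, sample in enumerate(matrix.samples):
            g = matrix.gt[i, on]
            called = g != MISSING
            if called.sum() == 0:
                continue
            idx = on[called]
            obs_het = matrix.gt[i, idx] == HET
            pos = pos_arr[idx]
            dist = np.empty(len(idx), dtype=np.int64)
            dist[0] = 0
            dist[1:] = np.diff(pos)
            states = _viterbi_path(obs_het, allele_freqs[idx], dist, config)
            segments.extend(
                _segments_from_states(
                    states, obs_het, pos, sample, str(chrom), config.min_hom_sites
                )
            )
    return segments


def froh(segments: list[ROHSegment], config: RohConfig | None = None,
         sample_id: str | None = None) -> float:
    """Fraction of the autosomal genome in ROHs longer than the threshold."""
    config = config or RohConfig()
    total = sum(
        s.length
        for s in segments
        if s.length > config.min_segment_length
        and (sample_id is None or s.sample_id == sample_id)
    )
    return total / config.genome_length


def froh_per_sample(
    segments: list[ROHSegment], samples: list[str], config: RohConfig | None = None
) -> pd.Series:
    config = config or RohConfig()
    return pd.Series(
        {s: froh(segments, config, sample_id=s) for s in samples}, name="froh"
    )


def segments_to_bed(segments: list[ROHSegment]) -> pd.DataFrame:
    """Convert 1-based inclusive segments to BED (0-based, half-open)."""
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in segments],
            "start": [s.start - 1 for s in segments],
            "end": [s.end for s in segments],
            "name": [s.sample_id for s in segments],
            "n_sites": [s.n_sites for s in segments],
        }
    )
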