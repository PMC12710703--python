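"""Shared in-memory containers for genotype data.

Genotypes are held as a dense ``samples x sites`` matrix of small integer
codes, mirroring how a multi-sample VCF is consumed after splitting
multi-allelic records:

* ``0`` homozygous reference
* ``1`` heterozygous
* ``2`` homozygous alternate
* ``-1`` missing

Per-genotype read metadata (DP, GQ and the two allelic depths) live in
parallel integer matrices; ``-1`` marks "not recorded".  Site-level
metadata (coordinates, alleles, impact category, ...) travels alongside as
a :class:`pandas.DataFrame` produced by :func:`make_site_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

#: transition pairs on the purine / pyrimidine axes
_TRANSITIONS = {frozenset(("A", "G")), frozenset(("C", "T"))}

SITE_COLUMNS = ("chrom", "pos", "ref", "alt", "is_transition", "impact")


def is_transition(ref: str, alt: str) -> bool:
    """True iff {ref, alt} is {A,G} or {C,T}."""
    return frozenset((ref.upper(), alt.upper())) in _TRANSITIONS


def make_site_table(
    chrom: Sequence[str],
    pos: Sequence[int],
    ref: Sequence[str],
    alt: Sequence[str],
    **extra,
) -> pd.DataFrame:
    """Assemble a site table with the canonical columns.

    ``is_transition`` is derived from the alleles; additional per-site
    columns (``impact``, ``qual``, ``ancestral``, ground-truth flags, ...)
    are passed as keyword arrays.
    """
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": np.asarray(ref, dtype=object),
            "alt": np.asarray(alt, dtype=object),
        }
    )
    df["is_transition"] = [is_transition(r, a) for r, a in zip(df["ref"], df["alt"])]
    if "impact" not in extra:
        df["impact"] = "MODIFIER"
    for key, val in extra.items():
        df[key] = val
    return df


@dataclass
class GenotypeMatrix:
    """Diploid calls for ``n_samples x n_sites`` with optional read metadata.

    Attributes
    ----------
    samples
        Sample identifiers, row order of every matrix.
    gt
        int8 matrix of genotype codes (0/1/2/-1).
    dp, gq, ad_ref, ad_alt
        Optional int32 matrices of per-genotype depth, genotype quality and
        allelic depths; ``None`` when the source carried no such fields.
    """

    samples: list[str]
    gt: np.ndarray
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.ndim != 2:
            raise ValueError("gt must be 2-D (samples x sites)")
        if len(self.samples) != self.gt.shape[0]:
            raise ValueError(
                f"{len(self.samples)} sample names for {self.gt.shape[0]} genotype rows"
            )
        for name in ("dp", "gq", "ad_ref", "ad_alt"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.int32)
                if arr.shape != self.gt.shape:
                    raise ValueError(f"{name} shape {arr.shape} != gt shape {self.gt.shape}")
                setattr(self, name, arr)

    # -- basic geometry ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.gt.shape[0]

    @property
    def n_sites(self) -> int:
        return self.gt.shape[1]

    def has_allelic_depths(self) -> bool:
        return self.ad_ref is not None and self.ad_alt is not None

    # -- derived quantities --------------------------------------------
    def alt_allele_counts(self) -> np.ndarray:
        """Per-site alternate allele count over non-missing genotypes."""
        g = self.gt
        return np.where(g > 0, g, 0).sum(axis=0)

    def called_allele_counts(self) -> np.ndarray:
        """Per-site number of called gene copies (2 x non-missing genotypes)."""
        return 2 * (self.gt != MISSING).sum(axis=0)

    def missing_fraction(self) -> np.ndarray:
        return (self.gt == MISSING).mean(axis=0)

    # -- subsetting ----------------------------------------------------
    def _map(self, fn) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            gt=fn(self.gt),
            dp=None if self.dp is None else fn(self.dp),
            gq=None if self.gq is None else fn(self.gq),
            ad_ref=None if self.ad_ref is None else fn(self.ad_ref),
            ad_alt=None if self.ad_alt is None else fn(self.ad_alt),
        )

    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return self._map(lambda a: a[:, index].copy())

    def take_samples(self, rows: Iterable[int]) -> "GenotypeMatrix":
        rows = np.asarray(list(rows))
        out = self._map(lambda a: a[rows].copy())
        out.samples = [self.samples[i] for i in rows]
        return out

    def copy(self) -> "GenotypeMatrix":
        return self._map(lambda a: a.copy())

    def equals(self, other: "GenotypeMatrix") -> bool:
        if self.samples != other.samples:
            return False
        for name in ("gt", "dp", "gq", "ad_ref", "ad_alt"):
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return True


def concat_samples(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two cohorts sharing one site table (historical first)."""
    if a.n_sites != b.n_sites:
        raise ValueError("cohorts must share one site table")

    def cat(x, y, fill):
        if x is None and y is None:
            return None
        if x is None:
            x = np.full(a.gt.shape, fill, dtype=np.int32)
        if y is None:
            y = np.full(b.gt.shape, fill, dtype=np.int32)
        return np.vstack([x, y])

    return GenotypeMatrix(
        samples=list(a.samples) + list(b.samples),
        gt=np.vstack([a.gt, b.gt]),
        dp=cat(a.dp, b.dp, -1),
        gq=cat(a.gq, b.gq, -1),
        ad_ref=cat(a.ad_ref, b.ad_ref, -1),
        ad_alt=cat(a.ad_alt, b.ad_alt, -1),
    )
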