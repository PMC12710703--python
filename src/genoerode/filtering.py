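"""Site- and genotype-level filters that build a harmonized "temporal
dataset" from mixed historical (low-coverage, damage-prone) and
contemporary genomes.

Three layers, mirroring how such datasets are curated in practice:

* :func:`filter_sites` - record-level hygiene: biallelic autosomal SNPs
  passing QUAL and missingness thresholds.
* :func:`filter_genotypes_contemporary` - depth/quality masking of
  individual genotypes in high-coverage contemporary samples.
* :func:`harmonize_temporal` - the low-coverage harmonization: a minimum
  read depth on the variant allele, an allelic-balance check on
  heterozygotes with recoding to the majority-read homozygote, and removal
  of low-count transition sites, which in historical DNA are
  overwhelmingly post-mortem deamination artifacts.

All filters preserve site order, are idempotent, and report what they
removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtering stack.

    Defaults follow the conventions of low-coverage temporal studies:
    QUAL > 40 and per-site missingness < 0.001 at the record level;
    contemporary genotypes need DP >= 6 and GQ > 15; the temporal
    harmonization needs >= 3 reads on the variant allele, heterozygote
    allelic balance inside [0.35, 0.75] (closed interval), and at least 3
    variant-allele copies cohort-wide for a transition site to survive.
    """

    min_qual: float = 40.0
    max_missing_fraction: float = 0.001
    contemporary_min_dp: int = 6
    contemporary_min_gq: int = 15  # genotypes must satisfy GQ > this bound
    min_variant_depth: int = 3
    balance_low: float = 0.35
    balance_high: float = 0.75
    min_transition_count: int = 3
    excluded_contigs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.balance_low < self.balance_high < 1.0:
            raise ValueError("need 0 < balance_low < balance_high < 1")
        for name in ("contemporary_min_dp", "min_variant_depth", "min_transition_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class FilterReport:
    """Per-rule accounting of removed sites and altered genotypes."""

    rules: list[dict] = field(default_factory=list)

    def add(self, rule: str, sites_removed: int = 0,
            genotypes_recoded: int = 0, genotypes_missing: int = 0) -> None:
        self.rules.append(
            {
                "rule": rule,
                "sites_removed": sites_removed,
                "genotypes_recoded": genotypes_recoded,
                "genotypes_missing": genotypes_missing,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rules,
            columns=["rule", "sites_removed", "genotypes_recoded", "genotypes_missing"],
        )


def _check_aligned(matrix: GenotypeMatrix, sites: pd.DataFrame) -> None:
    if matrix.n_sites != len(sites):
        raise ValueError(
            f"matrix has {matrix.n_sites} sites but site table has {len(sites)}"
        )


def filter_sites(
    matrix: GenotypeMatrix,
    sites: pd.DataFrame,
    config: FilterConfig | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, FilterReport]:
    """Record-level filter: QUAL, missingness and contig exclusion.

    Site order is preserved.  Non-biallelic records never reach this layer
    (the VCF reader drops them and reports counts); a ``qual`` column is
    honoured when present and ignored otherwise.
    """
    config = config or FilterConfig()
    _check_aligned(matrix, sites)
    report = FilterReport()
    keep = np.ones(len(sites), dtype=bool)

    if config.excluded_contigs:
        on_excluded = sites["chrom"].isin(config.excluded_contigs).to_numpy()
        report.add("non_autosomal_contig", sites_removed=int(on_excluded.sum()))
        keep &= ~on_excluded

    if "qual" in sites:
        qual = sites["qual"].to_numpy(dtype=float)
        bad_qual = keep & ~np.isnan(qual) & (qual <= config.min_qual)
        report.add("qual", sites_removed=int(bad_qual.sum()))
        keep &= ~bad_qual

    miss = matrix.missing_fraction()
    bad_miss = keep & (miss >= config.max_missing_fraction)
    report.add("missingness", sites_removed=int(bad_miss.sum()))
    keep &= ~bad_miss

    idx = np.flatnonzero(keep)
    return matrix.take_sites(idx), sites.iloc[idx].reset_index(drop=True), report


def filter_genotypes_contemporary(
    matrix: GenotypeMatrix,
    config: FilterConfig | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Mask genotypes below the contemporary depth/quality thresholds.

    A genotype survives iff DP >= contemporary_min_dp and
    GQ > contemporary_min_gq; everything else becomes missing.  Idempotent:
    masked genotypes carry no DP/GQ and stay missing.
    """
    config = config or FilterConfig()
    if matrix.dp is None or matrix.gq is None:
        raise ValueError("contemporary genotype filter needs DP and GQ fields")
    out = matrix.copy()
    called = out.gt != MISSING
    bad = called & (
        (out.dp < config.contemporary_min_dp) | (out.gq <= config.contemporary_min_gq)
    )
    out.gt[bad] = MISSING
    report = FilterReport()
    report.add("contemporary_dp_gq", genotypes_missing=int(bad.sum()))
    return out, report


def harmonize_temporal(
    matrix: GenotypeMatrix,
    sites: pd.DataFrame,
    config: FilterConfig | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, FilterReport]:
    """Harmonize a mixed historical/contemporary genotype matrix.

    Three ordered rules:

    (i)   genotypes asserting the variant allele (het or hom-alt) with
          fewer than ``min_variant_depth`` alternate reads become missing;
    (ii)  heterozygotes whose alternate-read fraction falls outside
          [balance_low, balance_high] are recoded homozygous for the
          allele with more reads (ties go to the reference allele);
    (iii) transition sites whose variant-allele count across all retained
          genotypes is below ``min_transition_count`` are removed outright
          (the deamination guard; transversions are exempt).
    """
    config = config or FilterConfig()
    _check_aligned(matrix, sites)
    if not matrix.has_allelic_depths():
        raise ValueError(
            "temporal harmonization needs allelic depths (AD) for all samples; "
            f"first sample lacking them: {matrix.samples[0]!r}"
        )
    out = matrix.copy()
    report = FilterReport()

    carries_variant = (out.gt == HET) | (out.gt == HOM_ALT)
    ad_known = out.ad_alt >= 0
    no_ad = carries_variant & ~ad_known
    if no_ad.any():
        i = int(np.argwhere(no_ad.any(axis=1))[0][0])
        raise ValueError(
            f"sample {out.samples[i]!r} asserts a variant without allelic depths"
        )

    # (i) variant-allele depth
    low_support = carries_variant & (out.ad_alt < config.min_variant_depth)
    out.gt[low_support] = MISSING
    report.add("variant_allele_depth", genotypes_missing=int(low_support.sum()))

    # (ii) heterozygote allelic balance
    het = out.gt == HET
    total = out.ad_ref + out.ad_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        balance = np.where(total > 0, out.ad_alt / np.maximum(total, 1), np.nan)
    off = het & (
        (balance < config.balance_low) | (balance > config.balance_high)
    )
    to_alt = off & (out.ad_alt > out.ad_ref)
    to_ref = off & ~to_alt  # ties recode toward the reference allele
    out.gt[to_alt] = HOM_ALT
    out.gt[to_ref] = HOM_REF
    report.add("mendelian_balance", genotypes_recoded=int(off.sum()))

    # (iii) low-count transitions (deamination guard)
    alt_count = out.alt_allele_counts()
    is_ti = sites["is_transition"].to_numpy(dtype=bool)
    drop = is_ti & (alt_count < config.min_transition_count)
    report.add("low_count_transition", sites_removed=int(drop.sum()))
    idx = np.flatnonzero(~drop)
    return out.take_sites(idx), sites.iloc[idx].reset_index(drop=True), report


def transversions_only(
    sites: pd.DataFrame,
    matrix: GenotypeMatrix | None = None,
) -> tuple[pd.DataFrame, GenotypeMatrix | None, FilterReport]:
    """Restrict to transversion sites - the damage-proof validation subset.

    Transitions dominate post-mortem deamination, so transversions act as
    a control dataset for any statistic computed from historical DNA.
    """
    is_tv = ~sites["is_transition"].to_numpy(dtype=bool)
    report = FilterReport()
    report.add("transitions_excluded", sites_removed=int((~is_tv).sum()))
    idx = np.flatnonzero(is_tv)
    sub_sites = sites.iloc[idx].reset_index(drop=True)
    sub_matrix = matrix.take_sites(idx) if matrix is not None else None
    return sub_sites, sub_matrix, report
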