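"""Ancestral polarization, potential/realized mutation load, the R_x/y
statistic with chromosome-jackknife confidence intervals, and cohort
comparison tests.

Polarization follows the outgroup-plus-frequency rule used in comparative
cetacean genomics: an allele is called ancestral iff it is near-fixed
(frequency above a threshold, 0.95 by default, in the pooled samples) AND
matches at least one outgroup genome; the other allele is derived.  Sites
where no allele qualifies are dropped and counted.

R_x/y compares the frequency-weighted derived-allele burden of cohort x
against cohort y within one impact category C:

    L_x,y(C) = sum_{i in C} f_i^x (1 - f_i^y),    R_x/y = L_x,y / L_y,x

where f_i = d_i / n_i is the derived-allele frequency among called gene
copies.  R > 1 means relative accumulation of derived alleles in x.
Uncertainty comes from a delete-one jackknife over autosomes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix, MISSING

IMPACT_LEVELS = ("MODIFIER", "LOW", "MODERATE", "HIGH")


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

@dataclass
class PolarizedSiteSet:
    """Sites with a resolved derived allele.

    ``sites`` carries the retained rows of the input site table plus a
    ``derived`` column ("alt" or "ref"); ``derived_dosage`` is the
    per-sample count of derived alleles (0/1/2, -1 missing), aligned to
    ``sites``; ``n_dropped`` counts sites where no allele qualified as
    ancestral.
    """

    sites: pd.DataFrame
    derived_dosage: np.ndarray
    samples: list[str]
    n_dropped: int


def polarize(
    matrix: GenotypeMatrix,
    sites: pd.DataFrame,
    outgroup: pd.Series | np.ndarray,
    freq_threshold: float = 0.95,
) -> PolarizedSiteSet:
    """Resolve the ancestral/derived identity of each biallelic site."""
    if matrix.n_sites != len(sites):
        raise ValueError("matrix and site table are misaligned")
    outgroup = np.asarray(outgroup, dtype=object)
    if len(outgroup) != len(sites):
        raise ValueError("need one outgroup allele per site")

    alt_count = matrix.alt_allele_counts().astype(float)
    called = matrix.called_allele_counts().astype(float)
    with np.errstate(invalid="ignore"):
        f_alt = np.where(called > 0, alt_count / np.maximum(called, 1), np.nan)
    f_ref = 1.0 - f_alt

    ref = sites["ref"].to_numpy(dtype=object)
    alt = sites["alt"].to_numpy(dtype=object)
    ref_anc = (f_ref > freq_threshold) & (outgroup == ref)
    alt_anc = (f_alt > freq_threshold) & (outgroup == alt)
    # with threshold > 0.5 both alleles can never qualify simultaneously
    assert not (ref_anc & alt_anc).any(), "both alleles qualified as ancestral"
    keep = (ref_anc | alt_anc) & (called > 0)

    idx = np.flatnonzero(keep)
    derived = np.where(ref_anc[idx], "alt", "ref")
    gt = matrix.gt[:, idx]
    dosage = np.where(gt == MISSING, -1, gt).astype(np.int8)
    flip = derived == "ref"
    dosage[:, flip] = np.where(
        dosage[:, flip] == -1, -1, 2 - dosage[:, flip]
    ).astype(np.int8)

    out_sites = sites.iloc[idx].reset_index(drop=True).copy()
    out_sites["derived"] = derived
    return PolarizedSiteSet(
        sites=out_sites,
        derived_dosage=dosage,
        samples=list(matrix.samples),
        n_dropped=int(len(sites) - keep.sum()),
    )


# ---------------------------------------------------------------------------
# per-sample load
# ---------------------------------------------------------------------------

def load_per_sample(
    polarized: PolarizedSiteSet,
    category: str | None = None,
) -> pd.DataFrame:
    """Potential and realized mutation load per sample (and category).

    Potential load counts the sites where a sample carries at least one
    derived allele; realized load is the fraction of those sites that are
    homozygous derived (NaN when the sample carries none).
    """
    cats = [category] if category else list(IMPACT_LEVELS)
    impact = polarized.sites["impact"].to_numpy(dtype=object)
    rows = []
    for cat in cats:
        on = impact == cat
        d = polarized.derived_dosage[:, on]
        potential = (d > 0).sum(axis=1)
        hom = (d == 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            realized = np.where(potential > 0, hom / np.maximum(potential, 1), np.nan)
        for i, s in enumerate(polarized.samples):
            rows.append(
                {
                    "sample_id": s,
                    "category": cat,
                    "potential": int(potential[i]),
                    "realized": float(realized[i]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# R_x/y
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RxyResult:
    category: str
    estimate: float
    jackknife_mean: float
    se: float
    ci_low: float
    ci_high: float
    n_blocks: int
    n_sites: int


def _freqs(dosage: np.ndarray, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site derived frequency and called-copy count within a cohort."""
    d = dosage[rows]
    called = d >= 0
    n = 2 * called.sum(axis=0)
    dsum = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        f = np.where(n > 0, dsum / np.maximum(n, 1), np.nan)
    return f, n


def _l_sums(fx: np.ndarray, fy: np.ndarray) -> tuple[float, float]:
    lxy = float(np.sum(fx * (1.0 - fy)))
    lyx = float(np.sum(fy * (1.0 - fx)))
    return lxy, lyx


def rxy(
    polarized: PolarizedSiteSet,
    cohorts: pd.Series | dict,
    x: str,
    y: str,
    category: str,
    ci_level: float = 0.95,
) -> RxyResult:
    """R_x/y for one impact category with a delete-one-autosome jackknife.

    Sites enter when they belong to the category, both cohorts have called
    gene copies, and the union of the cohorts carries at least one derived
    allele.  ``cohorts`` maps sample_id -> cohort label.
    """
    if isinstance(cohorts, dict):
        cohorts = pd.Series(cohorts)
    labels = cohorts.reindex(polarized.samples)
    if labels.isna().any():
        missing = [s for s, v in zip(polarized.samples, labels) if pd.isna(v)]
        raise ValueError(f"samples without cohort label: {missing}")
    rows_x = np.flatnonzero((labels == x).to_numpy())
    rows_y = np.flatnonzero((labels == y).to_numpy())
    if len(rows_x) == 0 or len(rows_y) == 0:
        raise ValueError(f"empty cohort among {x!r}, {y!r}")

    impact = polarized.sites["impact"].to_numpy(dtype=object)
    on_cat = impact == category
    fx_all, nx = _freqs(polarized.derived_dosage, rows_x)
    fy_all, ny = _freqs(polarized.derived_dosage, rows_y)
    usable = on_cat & (nx > 0) & (ny > 0)
    with np.errstate(invalid="ignore"):
        has_derived = (np.nan_to_num(fx_all) + np.nan_to_num(fy_all)) > 0
    usable &= has_derived
    idx = np.flatnonzero(usable)
    if len(idx) == 0:
        raise ValueError(f"no usable sites in category {category!r}")

    fx, fy = fx_all[idx], fy_all[idx]
    lxy, lyx = _l_sums(fx, fy)
    if lyx == 0:
        raise ValueError("L_y,x is zero: R_x/y undefined")
    estimate = lxy / lyx

    chrom = polarized.sites["chrom"].to_numpy(dtype=object)[idx]
    blocks = pd.unique(chrom)
    reps = []
    for b in blocks:
        off = chrom != b
        lxy_b, lyx_b = _l_sums(fx[off], fy[off])
        if lyx_b > 0:
            reps.append(lxy_b / lyx_b)
    reps = np.asarray(reps, dtype=float)
    n_b = len(reps)
    if n_b >= 2:
        jk_mean = float(reps.mean())
        se = math.sqrt((n_b - 1) / n_b * float(np.sum((reps - jk_mean) ** 2)))
    else:
        jk_mean, se = estimate, float("nan")
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return RxyResult(
        category=category,
        estimate=estimate,
        jackknife_mean=jk_mean,
        se=se,
        ci_low=jk_mean - z * se,
        ci_high=jk_mean + z * se,
        n_blocks=n_b,
        n_sites=len(idx),
    )


def rxy_table(polarized, cohorts, x, y, categories=IMPACT_LEVELS) -> pd.DataFrame:
    rows = []
    for cat in categories:
        try:
            r = rxy(polarized, cohorts, x, y, cat)
        except ValueError:
            continue
        rows.append(
            {
                "category": r.category, "estimate": r.estimate,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
                "se": r.se, "n_blocks": r.n_blocks, "n_sites": r.n_sites,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------

def _u_statistic(xs: np.ndarray, ys: np.ndarray) -> float:
    """Mann-Whitney U of x over y with the midrank tie convention."""
    u = 0.0
    for xv in xs:
        u += np.sum(xv > ys) + 0.5 * np.sum(xv == ys)
    return float(u)


def compare_cohorts(
    values_x, values_y, exact_max_total: int = 20
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two cohorts.

    For small samples (total size <= ``exact_max_total``) the p-value is
    exact: every assignment of the pooled values into the two group sizes
    is enumerated and assignments with |U - E[U]| at least as extreme as
    observed are counted (this handles ties naturally).  Larger samples
    use the tie-corrected normal approximation.

    Returns ``(U, p_value)`` with U measured for the first cohort.
    """
    xs = np.asarray(values_x, dtype=float)
    ys = np.asarray(values_y, dtype=float)
    if len(xs) == 0 or len(ys) == 0:
        raise ValueError("both cohorts need at least one value")
    u_obs = _u_statistic(xs, ys)
    n_x, n_y = len(xs), len(ys)

    if n_x + n_y <= exact_max_total:
        pooled = np.concatenate([xs, ys])
        mu = n_x * n_y / 2.0
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n_x + n_y), n_x):
            take = np.zeros(n_x + n_y, dtype=bool)
            take[list(combo)] = True
            u = _u_statistic(pooled[take], pooled[~take])
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
        return u_obs, count / total

    res = stats.mannwhitneyu(xs, ys, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)
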