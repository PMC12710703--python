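"""Reading and writing the on-disk formats of the pipeline.

VCF 4.2 is the interchange format for genotypes: the writer emits
GT:DP:AD:GQ per genotype plus an ``IMPACT`` INFO field; the reader (built
on :mod:`cyvcf2`) keeps biallelic SNPs only and records how many records
were dropped as indels or multi-allelic.  Cohort membership travels in a
plain TSV (sample_id, cohort, mean_depth, sampling_year).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import GenotypeMatrix, MISSING, make_site_table

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    path: str | os.PathLike,
    matrix: GenotypeMatrix,
    sites: pd.DataFrame,
    contig_lengths: dict[str, int] | None = None,
    source: str = "genoerode",
) -> None:
    """Write a multi-sample VCF 4.2 (uncompressed text).

    Site order follows ``sites``; per-genotype FORMAT fields are emitted
    when the matrix carries them (GT always; DP/AD/GQ when present).
    Ground-truth columns such as ``is_artifact`` or ``s`` are deliberately
    not written.
    """
    if len(sites) != matrix.n_sites:
        raise ValueError("site table and genotype matrix are misaligned")
    has_depth = matrix.dp is not None
    has_ad = matrix.has_allelic_depths()
    has_gq = matrix.gq is not None
    fmt_keys = ["GT"]
    if has_depth:
        fmt_keys.append("DP")
    if has_ad:
        fmt_keys.append("AD")
    if has_gq:
        fmt_keys.append("GQ")
    fmt = ":".join(fmt_keys)

    if contig_lengths is None:
        contig_lengths = {}
        for chrom, grp in sites.groupby("chrom", sort=False):
            contig_lengths[str(chrom)] = int(grp["pos"].max()) + 1000

    lines = ["##fileformat=VCFv4.2", f"##source={source}"]
    for chrom, length in contig_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        '##INFO=<ID=IMPACT,Number=1,Type=String,'
        'Description="Predicted functional impact category">'
    )
    lines.append(
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if has_depth:
        lines.append(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
        )
    if has_ad:
        lines.append(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">'
        )
    if has_gq:
        lines.append(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">'
        )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )

    qual = sites["qual"] if "qual" in sites else None
    anc = sites["ancestral"] if "ancestral" in sites else None
    impact = sites["impact"] if "impact" in sites else None
    gt, dp, gq = matrix.gt, matrix.dp, matrix.gq
    adr, ada = matrix.ad_ref, matrix.ad_alt
    for j in range(len(sites)):
        row = sites.iloc[j]
        info_parts = []
        if impact is not None:
            info_parts.append(f"IMPACT={impact.iloc[j]}")
        if anc is not None and anc.iloc[j] is not None:
            info_parts.append(f"AA={anc.iloc[j]}")
        info = ";".join(info_parts) if info_parts else "."
        q = "." if qual is None else f"{qual.iloc[j]:g}"
        cols = [
            str(row["chrom"]), str(int(row["pos"])), ".", str(row["ref"]),
            str(row["alt"]), q, "PASS", info, fmt,
        ]
        for i in range(matrix.n_samples):
            parts = [_GT_CODE[int(gt[i, j])]]
            if has_depth:
                parts.append("." if dp[i, j] < 0 else str(dp[i, j]))
            if has_ad:
                parts.append(
                    "." if adr[i, j] < 0 else f"{adr[i, j]},{ada[i, j]}"
                )
            if has_gq:
                parts.append("." if gq[i, j] < 0 else str(gq[i, j]))
            cols.append(":".join(parts))
        lines.append("\t".join(cols))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass
class VcfReadResult:
    matrix: GenotypeMatrix
    sites: pd.DataFrame
    n_dropped_multiallelic: int
    n_dropped_indel: int


def read_vcf(path: str | os.PathLike) -> VcfReadResult:
    """Read a multi-sample VCF into a GenotypeMatrix + site table.

    Only biallelic SNPs are kept; dropped record counts are reported so a
    filter log can account for every input line.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    impacts: list[str] = []
    ancestrals: list[str | None] = []
    gts: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    gqs: list[np.ndarray] = []
    adrs: list[np.ndarray] = []
    adas: list[np.ndarray] = []
    n_multi = 0
    n_indel = 0
    any_dp = any_gq = any_ad = False

    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_indel += 1
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        quals.append(var.QUAL if var.QUAL is not None else np.nan)
        impacts.append(var.INFO.get("IMPACT", "MODIFIER"))
        ancestrals.append(var.INFO.get("AA"))

        types = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.full(len(samples), MISSING, dtype=np.int8)
        gt[types == 0] = 0
        gt[types == 1] = 1
        gt[types == 3] = 2
        gts.append(gt)

        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            any_dp = True
            dp = dp.reshape(-1).astype(np.int32)
            dp[dp < 0] = -1
        dps.append(dp)
        try:
            gq = var.format("GQ")
        except KeyError:
            gq = None
        if gq is not None:
            any_gq = True
            gq = gq.reshape(-1).astype(np.int32)
            gq[gq < 0] = -1
        gqs.append(gq)
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            any_ad = True
            ad = ad.astype(np.int32)
            adr = ad[:, 0].copy()
            ada = ad[:, 1].copy()
            adr[adr < 0] = -1
            ada[ada < 0] = -1
        else:
            adr = ada = None
        adrs.append(adr)
        adas.append(ada)

    n_sites = len(chroms)
    n_samp = len(samples)

    def stack(cols, present, fill=-1):
        if not present:
            return None
        out = np.full((n_samp, n_sites), fill, dtype=np.int32)
        for j, c in enumerate(cols):
            if c is not None:
                out[:, j] = c
        return out

    gt_mat = (
        np.stack(gts, axis=1)
        if n_sites
        else np.empty((n_samp, 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(
        samples=samples,
        gt=gt_mat,
        dp=stack(dps, any_dp),
        gq=stack(gqs, any_gq),
        ad_ref=stack(adrs, any_ad),
        ad_alt=stack(adas, any_ad),
    )
    sites = make_site_table(
        chrom=chroms, pos=poss, ref=refs, alt=alts,
        impact=np.array(impacts, dtype=object),
        qual=np.array(quals, dtype=float),
        ancestral=np.array(ancestrals, dtype=object),
    )
    return VcfReadResult(
        matrix=matrix, sites=sites,
        n_dropped_multiallelic=n_multi, n_dropped_indel=n_indel,
    )


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ("sample_id", "cohort", "mean_depth", "sampling_year")


def write_cohort_table(path: str | os.PathLike, cohorts: pd.DataFrame) -> None:
    missing = set(COHORT_COLUMNS) - set(cohorts.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    cohorts.loc[:, COHORT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cohort_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    return df


def make_cohort_table(
    sample_ids: list[str],
    cohort: str,
    mean_depth: float,
    sampling_year: int,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": cohort,
            "mean_depth": mean_depth,
            "sampling_year": sampling_year,
        }
    )
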