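"""End-to-end orchestration: simulate -> filter -> diversity -> load ->
demography, with a consolidated report and a provenance manifest.

The pipeline is configured by a nested plain-text (YAML) configuration
that round-trips losslessly; unknown keys are rejected by name.  Every
run writes a ``manifest.yaml`` recording the configuration hash, the
seed and the package version, so identical configurations reproduce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import demography as demo
from . import diversity, filtering, load as load_mod, simdata, vcfio
from .core import GenotypeMatrix, concat_samples


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _from_dict(cls, data: dict, path: str):
    """Build a dataclass from a mapping, rejecting unknown keys by name."""
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    kwargs = {f.name: data[f.name] for f in dataclasses.fields(cls) if f.name in data}
    return cls(**kwargs)


@dataclass
class SimulateConfig:
    enabled: bool = True
    n_genes: int = 200
    gene_length: int = 1000
    n_chromosomes: int = 2
    mu: float = 1.12e-8
    rescale_lambda: float = 20.0
    scale_bottleneck: bool = False
    sample_size: int = 12
    deamination_rate: float = 0.05
    target_depth: float = 6.0
    p_neutral: float = 0.3
    gamma_shape: float = 0.186
    mean_s: float = -0.01
    h: float = 0.5
    historical_year: int = 1920
    contemporary_year: int = 2020
    # epochs default to the whaling-era bottleneck model
    epochs: list = field(default_factory=lambda: [
        {"duration": 500_000, "n_start": 16_000, "n_end": 16_000, "shape": "constant"},
        {"duration": 5, "n_start": 16_000, "n_end": 375, "shape": "exponential"},
        {"duration": 10, "n_start": 375, "n_end": 8_000, "shape": "exponential"},
    ])


@dataclass
class FilterStageConfig:
    enabled: bool = True
    min_qual: float = 40.0
    max_missing_fraction: float = 1.01  # simulated calls have no missingness
    min_variant_depth: int = 3
    balance_low: float = 0.35
    balance_high: float = 0.75
    min_transition_count: int = 3


@dataclass
class DiversityStageConfig:
    enabled: bool = True
    min_hom_sites: int = 25
    min_segment_length: float = 10_000.0  # desk-scale genomes are short
    az_entry_rate: float = 6.7e-8
    az_exit_rate: float = 5e-9
    error_rate: float = 1e-4


@dataclass
class LoadStageConfig:
    enabled: bool = True
    freq_threshold: float = 0.95
    outgroup_divergence: float = 0.02
    x_cohort: str = "contemporary"
    y_cohort: str = "historical"


@dataclass
class DemographyStageConfig:
    enabled: bool = True
    estimator_dir: str | None = None  # read real estimator output if given
    n_runs: int = 40
    run_cv: float = 0.05
    n_generations: int = 40
    ne_nc_ratio: float = 4.0
    anchor_generation: int = 15
    gen_interval_years: float = 8.0
    catch_noise: float = 0.0


@dataclass
class PipelineConfig:
    seed: int = 1
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    filter: FilterStageConfig = field(default_factory=FilterStageConfig)
    diversity: DiversityStageConfig = field(default_factory=DiversityStageConfig)
    load: LoadStageConfig = field(default_factory=LoadStageConfig)
    demography: DemographyStageConfig = field(default_factory=DemographyStageConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        out = {}
        sections = {
            "simulate": SimulateConfig,
            "filter": FilterStageConfig,
            "diversity": DiversityStageConfig,
            "load": LoadStageConfig,
            "demography": DemographyStageConfig,
        }
        unknown = set(data) - set(sections) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "seed" in data:
            out["seed"] = int(data["seed"])
        for name, section_cls in sections.items():
            if name in data:
                out[name] = _from_dict(section_cls, data[name], name)
        return cls(**out)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    sc = cfg.simulate
    demography = simdata.DemographyModel(
        tuple(simdata.Epoch(**e) for e in sc.epochs)
    )
    dfe = simdata.DFEModel(
        p_neutral=sc.p_neutral, gamma_shape=sc.gamma_shape,
        mean_s=sc.mean_s, h=sc.h,
    )
    genome = simdata.GenomeModel(
        n_genes=sc.n_genes, gene_length=sc.gene_length,
        n_chromosomes=sc.n_chromosomes, mu=sc.mu,
    )
    if sc.rescale_lambda > 1:
        model = simdata.rescale_model(
            demography, dfe, genome, sc.rescale_lambda, sc.scale_bottleneck
        )
        rep = simdata.simulate_rescaled(
            model, sample_size=sc.sample_size, seed=cfg.seed
        )
    else:
        rep = simdata.simulate_replicate(
            demography, dfe, genome, sample_size=sc.sample_size, seed=cfg.seed
        )

    hist = rep.cohorts["pre_bottleneck"].matrix
    cont = rep.cohorts["post_recovery"].matrix
    merged = concat_samples(hist, cont)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20]))
    merged, sites = simdata.add_historical_artifacts(
        merged, rep.sites, sc.deamination_rate,
        target_depth=sc.target_depth,
        seed=int(rng.integers(0, 2**31 - 1)),
        carrier_samples=hist.samples,
    )
    outgroup = simdata.outgroup_alleles(
        sites, divergence=cfg.load.outgroup_divergence,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    sites = sites.copy()
    sites["outgroup"] = outgroup.to_numpy()

    cohorts = pd.concat(
        [
            vcfio.make_cohort_table(
                hist.samples, "historical", sc.target_depth, sc.historical_year
            ),
            vcfio.make_cohort_table(
                cont.samples, "contemporary", sc.target_depth, sc.contemporary_year
            ),
        ],
        ignore_index=True,
    )

    contigs = {
        f"chr{c + 1}": int(length)
        for c, length in enumerate(genome.chrom_lengths())
    }
    vcfio.write_vcf(outdir / "cohort.vcf", merged, sites, contig_lengths=contigs)
    vcfio.write_cohort_table(outdir / "cohorts.tsv", cohorts)
    truth_cols = [
        c for c in ("chrom", "pos", "ref", "alt", "is_transition", "impact",
                    "s", "is_artifact", "outgroup")
        if c in sites.columns
    ]
    sites[truth_cols].to_csv(outdir / "sites_truth.tsv", sep="\t", index=False)
    with open(outdir / "replicate_summary.yaml", "w") as fh:
        yaml.safe_dump(_jsonable(rep.summaries), fh, sort_keys=True)
    return {
        "replicate": rep,
        "matrix": merged,
        "sites": sites,
        "cohorts": cohorts,
        "genome": genome,
        "demography": demography,
        "summaries": rep.summaries,
    }


def _stage_filter(cfg: PipelineConfig, outdir: Path, sim: dict) -> dict:
    fc = cfg.filter
    config = filtering.FilterConfig(
        min_qual=fc.min_qual,
        max_missing_fraction=fc.max_missing_fraction,
        min_variant_depth=fc.min_variant_depth,
        balance_low=fc.balance_low,
        balance_high=fc.balance_high,
        min_transition_count=fc.min_transition_count,
    )
    matrix, sites = sim["matrix"], sim["sites"]
    m1, s1, rep1 = filtering.filter_sites(matrix, sites, config)
    m2, s2, rep2 = filtering.harmonize_temporal(m1, s1, config)
    report = pd.concat([rep1.to_frame(), rep2.to_frame()], ignore_index=True)
    report.to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    vcfio.write_vcf(outdir / "temporal.vcf", m2, s2)
    return {"matrix": m2, "sites": s2, "report": report}


def _stage_diversity(cfg: PipelineConfig, outdir: Path, filt: dict, sim: dict) -> dict:
    dc = cfg.diversity
    genome: simdata.GenomeModel = sim["genome"]
    roh_cfg = diversity.RohConfig(
        az_entry_rate=dc.az_entry_rate,
        az_exit_rate=dc.az_exit_rate,
        error_rate=dc.error_rate,
        min_hom_sites=dc.min_hom_sites,
        min_segment_length=dc.min_segment_length,
        genome_length=genome.total_length,
    )
    matrix, sites = filt["matrix"], filt["sites"]
    het = {
        s: diversity.genome_wide_heterozygosity(matrix.gt[i], genome.total_length)
        for i, s in enumerate(matrix.samples)
    }
    segments = diversity.call_roh(matrix, sites, config=roh_cfg)
    froh = diversity.froh_per_sample(segments, matrix.samples, roh_cfg)
    table = pd.DataFrame(
        {"sample_id": matrix.samples,
         "het": [het[s] for s in matrix.samples],
         "froh": froh.reindex(matrix.samples).to_numpy()}
    )
    table.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    diversity.segments_to_bed(segments).to_csv(
        outdir / "roh_segments.bed", sep="\t", index=False, header=False
    )
    return {"table": table, "segments": segments}


def _stage_load(cfg: PipelineConfig, outdir: Path, filt: dict, sim: dict) -> dict:
    lc = cfg.load
    matrix, sites = filt["matrix"], filt["sites"]
    polarized = load_mod.polarize(
        matrix, sites, sites["outgroup"], freq_threshold=lc.freq_threshold
    )
    cohorts = sim["cohorts"].set_index("sample_id")["cohort"]
    per_sample = load_mod.load_per_sample(polarized)
    per_sample["cohort"] = per_sample["sample_id"].map(cohorts)
    per_sample = per_sample[["sample_id", "cohort", "category", "potential", "realized"]]
    per_sample.to_csv(outdir / "load.tsv", sep="\t", index=False)

    rxy_df = load_mod.rxy_table(polarized, cohorts, lc.x_cohort, lc.y_cohort)
    rxy_df.to_csv(outdir / "rxy.tsv", sep="\t", index=False)

    tests = []
    for cat, grp in per_sample.groupby("category"):
        xs = grp.loc[grp["cohort"] == lc.x_cohort, "realized"].dropna()
        ys = grp.loc[grp["cohort"] == lc.y_cohort, "realized"].dropna()
        if len(xs) and len(ys):
            u, p = load_mod.compare_cohorts(xs, ys)
            tests.append({"category": cat, "statistic": "realized_load_U",
                          "U": u, "p_value": p})
    tests_df = pd.DataFrame(tests)
    tests_df.to_csv(outdir / "cohort_tests.tsv", sep="\t", index=False)
    return {"per_sample": per_sample, "rxy": rxy_df, "tests": tests_df,
            "n_dropped_polarization": polarized.n_dropped}


def _stage_demography(cfg: PipelineConfig, outdir: Path, sim: dict) -> dict:
    dc = cfg.demography
    sc = cfg.simulate
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**21]))
    if dc.estimator_dir:
        runs = demo.read_estimator_runs(dc.estimator_dir)
    else:
        # emulate estimator output from the true simulated demography
        demography: simdata.DemographyModel = sim["demography"]
        sizes = demography.size_trajectory()[::-1]  # generations before sampling
        ne_true = sizes[: dc.n_generations].astype(float)
        runs = simdata.synthetic_ne_runs(
            ne_true, n_runs=dc.n_runs, cv=dc.run_cv,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    gen_time = dc.gen_interval_years
    anchor = demo.CalibrationAnchor(
        anchor_generation=dc.anchor_generation,
        anchor_year=sc.contemporary_year - dc.anchor_generation * gen_time,
        sampling_year=sc.contemporary_year,
    )
    traj = demo.trajectory_report(runs, anchor=anchor, ratio=dc.ne_nc_ratio)
    traj.to_csv(outdir / "ne_trajectory.tsv", sep="\t", index=False)

    # synthetic catch record from the dated census trajectory
    nc_forward = traj.sort_values("year")
    catches = simdata.generate_catch_series(
        nc_forward["nc_mean"].to_numpy(),
        reporting_noise=dc.catch_noise,
        seed=int(rng.integers(0, 2**31 - 1)),
        years=nc_forward["year"].to_numpy()[1:],
    )
    catches.to_csv(outdir / "catches.csv", index=False)
    r, r2, p = demo.catch_correlation(traj, catches, dc.gen_interval_years)
    corr = {"pearson_r": r, "r_squared": r2, "p_value": p}
    with open(outdir / "catch_correlation.yaml", "w") as fh:
        yaml.safe_dump(corr, fh)
    return {"trajectory": traj, "catches": catches, "correlation": corr}


# ---------------------------------------------------------------------------
# report and driver
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def make_report(outputs: dict, cohorts: pd.DataFrame | None = None) -> str:
    """Assemble the consolidated run report from stage outputs.

    Numbers are copied from the stage tables, never recomputed.  Sample
    identifiers are cross-checked against the cohort table; an unknown
    sample is a validation error naming the identifier.
    """
    lines = ["# genoerode run report", ""]
    known = set(cohorts["sample_id"]) if cohorts is not None else None

    def check_samples(df, col, section):
        if known is None or col not in df:
            return
        alien = sorted(set(df[col]) - known)
        if alien:
            raise ValueError(
                f"{section}: sample {alien[0]!r} is absent from the cohort table"
            )

    if "summaries" in outputs:
        lines.append("## simulation")
        summ = outputs["summaries"]
        for label, c in summ.get("cohorts", {}).items():
            lines.append(
                f"cohort {label}: mean_het={c['mean_het']:.6g} "
                f"segregating={c['segregating_sites']}"
            )
        if "het_loss_pct" in summ:
            lines.append(f"het_loss_pct={summ['het_loss_pct']:.4g}")
        lines.append("")
    if "diversity" in outputs:
        lines.append("## diversity")
        df = outputs["diversity"]["table"]
        check_samples(df, "sample_id", "diversity")
        for _, row in df.iterrows():
            lines.append(
                f"{row['sample_id']}\thet={row['het']:.6g}\tfroh={row['froh']:.6g}"
            )
        lines.append("")
    else:
        lines.append("## diversity\n(not run)\n")
    if "load" in outputs:
        lines.append("## mutation load")
        df = outputs["load"]["per_sample"]
        check_samples(df, "sample_id", "load")
        agg = df.groupby(["cohort", "category"])[["potential", "realized"]].mean()
        for (cohort, cat), row in agg.iterrows():
            lines.append(
                f"{cohort}\t{cat}\tpotential={row['potential']:.4g}"
                f"\trealized={row['realized']:.4g}"
            )
        lines.append("")
        rxy_df = outputs["load"]["rxy"]
        if len(rxy_df):
            lines.append("## R_x/y")
            for _, row in rxy_df.iterrows():
                lines.append(
                    f"{row['category']}\tR={row['estimate']:.4g}"
                    f"\tCI=[{row['ci_low']:.4g}, {row['ci_high']:.4g}]"
                )
            lines.append("")
    else:
        lines.append("## mutation load\n(not run)\n")
    if "demography" in outputs:
        lines.append("## demography")
        corr = outputs["demography"]["correlation"]
        lines.append(
            f"catch correlation: r^2={corr['r_squared']:.4g} p={corr['p_value']:.3g}"
        )
        lines.append("")
    else:
        lines.append("## demography\n(not run)\n")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages in dependency order.

    Later stages require the simulate stage (this pipeline's data source);
    a disabled prerequisite is a configuration error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}

    if not config.simulate.enabled and (
        config.filter.enabled or config.diversity.enabled or config.load.enabled
    ):
        raise ValueError("filter/diversity/load stages require the simulate stage")

    if config.simulate.enabled:
        sim = _stage_simulate(config, outdir)
        outputs["simulate"] = sim
        outputs["summaries"] = sim["summaries"]
    if config.filter.enabled:
        filt = _stage_filter(config, outdir, outputs["simulate"])
        outputs["filter"] = filt
        if config.diversity.enabled:
            outputs["diversity"] = _stage_diversity(
                config, outdir, filt, outputs["simulate"]
            )
        if config.load.enabled:
            outputs["load"] = _stage_load(config, outdir, filt, outputs["simulate"])
    if config.demography.enabled:
        outputs["demography"] = _stage_demography(
            config, outdir, outputs.get("simulate", {})
        )

    cohorts = outputs.get("simulate", {}).get("cohorts")
    report = make_report(outputs, cohorts)
    (outdir / "report.txt").write_text(report)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "stages_run": [
            k for k in ("simulate", "filter", "diversity", "load", "demography")
            if k in outputs
        ],
        "config": config.to_dict(),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(_jsonable(manifest), fh, sort_keys=True)
    outputs["report"] = report
    outputs["manifest"] = manifest
    return outputs
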