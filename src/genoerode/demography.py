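"""Effective-population-size trajectory utilities.

This module consumes the per-run output tables of an LD-based Ne
estimator (one whitespace-delimited file per independent run: generation
column, Ne column, header lines skipped) and provides

* per-generation summaries (mean, median, percentile 95% CI),
* conversion to census size via a fixed Ne:Nc ratio (1:4 for baleen
  whales),
* generation-time calibration: anchoring a known historical event (e.g.
  the onset of mechanized whaling, 1904) to its estimated generation
  offset yields years per generation, which dates the whole trajectory,
* the G robustness statistic ``G = n * theta / Ne`` (n = sample size,
  theta = pairwise SNP comparisons); low G flags unreliable estimates,
* the correlation between the dated Ne trajectory and cumulative catch
  records.

The estimation algorithm itself is out of scope; only its outputs are
consumed.
"""

from __future__ import annotations

import glob
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CalibrationAnchor:
    """A dated demographic event at a known generation offset."""

    anchor_generation: int   # generations before sampling
    anchor_year: float       # calendar year of the event
    sampling_year: float     # calendar year of the sampled genomes

    def __post_init__(self) -> None:
        if self.anchor_generation <= 0:
            raise ValueError("anchor_generation must be positive")
        if self.sampling_year <= self.anchor_year:
            raise ValueError("sampling_year must postdate anchor_year")


def read_estimator_runs(paths_or_dir) -> pd.DataFrame:
    """Read per-run Ne output tables into a wide frame.

    Accepts a directory (every ``*.txt``/``*.out`` file inside, sorted) or
    an explicit list of paths.  Each file holds two whitespace-delimited
    numeric columns (generation, Ne); non-numeric header lines are
    skipped.  Returns columns ``generation, run_1, run_2, ...``.
    """
    if isinstance(paths_or_dir, (str, os.PathLike)) and os.path.isdir(paths_or_dir):
        paths = sorted(
            glob.glob(os.path.join(str(paths_or_dir), "*.txt"))
            + glob.glob(os.path.join(str(paths_or_dir), "*.out"))
        )
    else:
        paths = [str(p) for p in paths_or_dir]
    if not paths:
        raise ValueError("no estimator output files found")

    runs = []
    gens_ref = None
    for path in paths:
        gens, nes = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) < 2:
                    continue
                try:
                    g = float(parts[0])
                    ne = float(parts[1])
                except ValueError:
                    continue  # header line
                gens.append(g)
                nes.append(ne)
        if not gens:
            raise ValueError(f"no numeric rows in {path}")
        gens = np.asarray(gens)
        if gens_ref is None:
            gens_ref = gens
        elif len(gens) != len(gens_ref) or not np.allclose(gens, gens_ref):
            raise ValueError(f"{path} covers different generations than earlier runs")
        runs.append(np.asarray(nes))

    out = {"generation": gens_ref.astype(int)}
    for i, ne in enumerate(runs):
        out[f"run_{i + 1}"] = ne
    return pd.DataFrame(out)


def _run_columns(runs: pd.DataFrame) -> list[str]:
    return [c for c in runs.columns if c != "generation"]


def summarize_trajectory(runs: pd.DataFrame, ci_level: float = 0.95) -> pd.DataFrame:
    """Per-generation mean, median and percentile CI across estimator runs."""
    cols = _run_columns(runs)
    if len(cols) < 2:
        raise ValueError("need at least two estimator runs to summarize")
    values = runs[cols].to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("Ne values must be positive")
    lo = 100 * (0.5 - ci_level / 2)
    hi = 100 * (0.5 + ci_level / 2)
    return pd.DataFrame(
        {
            "generation": runs["generation"].to_numpy(),
            "ne_mean": values.mean(axis=1),
            "ne_median": np.median(values, axis=1),
            "ci_low": np.percentile(values, lo, axis=1),
            "ci_high": np.percentile(values, hi, axis=1),
            "n_runs": len(cols),
        }
    )


def ne_to_nc(traj: pd.DataFrame, ratio: float = 4.0) -> pd.DataFrame:
    """Census size from effective size, ``Nc = Ne * ratio`` (default 1:4)."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    out = traj.copy()
    for col in ("ne_mean", "ne_median", "ci_low", "ci_high"):
        if col in out:
            out[col.replace("ne_", "nc_") if col.startswith("ne_") else f"nc_{col}"] = (
                out[col] * ratio
            )
    return out


def calibrate_generation_time(anchor: CalibrationAnchor) -> float:
    """Years per generation implied by the anchored event."""
    return (anchor.sampling_year - anchor.anchor_year) / anchor.anchor_generation


def map_generations_to_years(
    traj: pd.DataFrame, gen_time: float, sampling_year: float
) -> pd.DataFrame:
    """Date a generations-before-sampling trajectory in calendar years."""
    if gen_time <= 0:
        raise ValueError("gen_time must be positive")
    out = traj.copy()
    out["year"] = sampling_year - out["generation"].to_numpy(dtype=float) * gen_time
    return out


def g_statistic(
    n: float, theta, ne, flag_threshold: float = 100.0
) -> pd.DataFrame:
    """G = n * theta / Ne with a low-confidence flag.

    ``theta`` is the number of pairwise SNP comparisons backing the
    estimate (per generation bin, or a single total applied to all bins);
    estimates with G at or below ``flag_threshold`` are flagged - values
    near 50 are conventionally treated as unreliable.
    """
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    ne_arr = np.atleast_1d(np.asarray(ne, dtype=float))
    if n <= 0 or (theta_arr <= 0).any() or (ne_arr <= 0).any():
        raise ValueError("n, theta and Ne must all be positive")
    theta_arr, ne_arr = np.broadcast_arrays(theta_arr, ne_arr)
    g = n * theta_arr / ne_arr
    return pd.DataFrame({"G": g, "low_confidence": g <= flag_threshold})


def catch_correlation(
    dated_traj: pd.DataFrame,
    catches: pd.DataFrame,
    gen_interval: float,
) -> tuple[float, float, float]:
    """Pearson correlation between generational Ne means and cumulative
    catches.

    Catches (columns ``year``, ``catches``) are accumulated forward in
    time, then each trajectory generation is assigned the cumulative total
    at the end of its ``gen_interval``-year bin (bins proceed backward
    from the youngest dated generation).  Returns ``(r, r^2, p)``; the
    p-value uses the t transformation with n-2 degrees of freedom.
    """
    if gen_interval <= 0:
        raise ValueError("gen_interval must be positive")
    if "year" not in dated_traj:
        raise ValueError("trajectory must be dated (map_generations_to_years)")
    cat = catches.sort_values("year")
    years = cat["year"].to_numpy(dtype=float)
    cum = np.cumsum(cat["catches"].to_numpy(dtype=float))

    traj_years = dated_traj["year"].to_numpy(dtype=float)
    ne = dated_traj["ne_mean"].to_numpy(dtype=float)
    lo, hi = years.min(), years.max()
    on = (traj_years >= lo - gen_interval) & (traj_years <= hi + gen_interval)
    if on.sum() < 3:
        raise ValueError("fewer than 3 trajectory points overlap the catch record")
    # cumulative catches up to (and including) each generation's year
    idx = np.searchsorted(years, traj_years[on], side="right") - 1
    cum_at = np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)
    ne_on = ne[on]
    if np.allclose(ne_on, ne_on[0]) or np.allclose(cum_at, cum_at[0]):
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(ne_on, cum_at)
    return float(r), float(r * r), float(p)


def trajectory_report(
    runs: pd.DataFrame,
    anchor: CalibrationAnchor | None = None,
    ratio: float = 4.0,
    sample_size: float | None = None,
    theta=None,
) -> pd.DataFrame:
    """One-stop dated trajectory table: summaries, Nc, years, G."""
    traj = summarize_trajectory(runs)
    traj = ne_to_nc(traj, ratio)
    if anchor is not None:
        gen_time = calibrate_generation_time(anchor)
        traj = map_generations_to_years(traj, gen_time, anchor.sampling_year)
    if sample_size is not None and theta is not None:
        gstat = g_statistic(sample_size, theta, traj["ne_mean"].to_numpy())
        traj["G"] = gstat["G"].to_numpy()
        traj["low_confidence"] = gstat["low_confidence"].to_numpy()
    return traj
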