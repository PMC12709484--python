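"""End-to-end group comparison: configuration, orchestration, report emission.

run_all sweeps both groups over the threshold grid once, derives the Df and
ln Dtf trajectories from the same pooled per-region values, computes the
group-averaged multifractal spectra and the IPR scan, and emits a JSON
report (plus raw CSVs and optional plots) whose numbers are all traceable to
the emitted artifacts.  Deterministic given the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boxcount import DEFAULT_BOX_SIZES
from .image_io import GrayImage, read_gray
from .ipr import DEFAULT_PIXEL_SIZES, ipr_scan
from .multifractal import (DEFAULT_EPS, DEFAULT_Q_GRID, average_spectra,
                           spectrum, spectrum_params)
from .thresholding import ThresholdSpec, threshold_grid
from .trajectory import TrajectoryCurve, optimal_threshold, pooled_region_values
from .transform import apply_transform, gaussian_fit

log = logging.getLogger("tissuefractal")


@dataclass
class RunConfig:
    """Fully serializable description of one comparison run."""

    group_a: list = field(default_factory=list)   # control image paths
    group_b: list = field(default_factory=list)   # disease image paths
    label_a: str = "control"
    label_b: str = "disease"
    threshold_start: int = 25
    threshold_stop: int = 155
    threshold_step: int = 5
    region_size: int = 60
    box_sizes: tuple = DEFAULT_BOX_SIZES
    q_grid: tuple = DEFAULT_Q_GRID
    eps_list: tuple = DEFAULT_EPS
    ipr_sizes: tuple = DEFAULT_PIXEL_SIZES
    min_region_support: int = 10
    seed: int = 0
    out_dir: str | None = None
    make_plots: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = [x.item() if hasattr(x, "item") else x for x in v]
        d["group_a"] = [str(p) for p in d["group_a"]]
        d["group_b"] = [str(p) for p in d["group_b"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for k in ("box_sizes", "q_grid", "eps_list", "ipr_sizes"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


def _contrast_dict(c) -> dict:
    return {
        "optimal_gray_level": c.optimal_threshold.gray_level,
        "optimal_percent": c.optimal_threshold.percent,
        "value_control": c.value_control,
        "value_disease": c.value_disease,
        "abs_diff": c.abs_diff,
        "percent_change": c.percent_change,
    }


def _nan_to_none(x):
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def _curve_dict(c: TrajectoryCurve) -> dict:
    return {
        "gray_levels": [t.gray_level for t in c.thresholds],
        "percents": [t.percent for t in c.thresholds],
        "mean": [_nan_to_none(float(v)) for v in c.mean_curve],
        "std": [_nan_to_none(float(v)) for v in c.std_curve],
        "n_regions": [int(n) for n in c.n_regions],
    }


def _group_sweeps(images, grid, config, label):
    """Df and lnDtf trajectories from a single pass of pooled region values."""
    means_df, stds_df, means_ln, stds_ln, ns_df, ns_ln = [], [], [], [], [], []
    pooled_per_t = []
    for t in grid:
        dfs = pooled_region_values(images, t, config.region_size, config.box_sizes)
        pooled_per_t.append(dfs)
        ns_df.append(dfs.size)
        means_df.append(float(dfs.mean()) if dfs.size else np.nan)
        stds_df.append(float(dfs.std(ddof=1)) if dfs.size > 1 else np.nan)
        dtf, _ = apply_transform(dfs)
        ln = np.log(dtf) if dtf.size else np.empty(0)
        ns_ln.append(ln.size)
        means_ln.append(float(ln.mean()) if ln.size else np.nan)
        stds_ln.append(float(ln.std(ddof=1)) if ln.size > 1 else np.nan)
    df_curve = TrajectoryCurve(tuple(grid), np.asarray(means_df),
                               np.asarray(stds_df), np.asarray(ns_df),
                               group_label=label, quantity="Df")
    ln_curve = TrajectoryCurve(tuple(grid), np.asarray(means_ln),
                               np.asarray(stds_ln), np.asarray(ns_ln),
                               group_label=label, quantity="lnDtf")
    return df_curve, ln_curve, pooled_per_t


def run_all(config: RunConfig, images_a=None, images_b=None) -> dict:
    """Execute the full multiparametric comparison.

    Images may be passed in memory (images_a/images_b); otherwise they are
    loaded from the paths in the config.  Returns the report as a dict; when
    config.out_dir is set, writes report.json, raw CSVs and (optionally)
    plots there.
    """
    if images_a is None:
        images_a = [read_gray(p) for p in config.group_a]
    if images_b is None:
        images_b = [read_gray(p) for p in config.group_b]
    if not images_a or not images_b:
        raise ValueError("both groups must contain at least one image")

    grid = threshold_grid(config.threshold_start, config.threshold_stop,
                          config.threshold_step)
    report: dict = {"config": config.to_dict(), "version": __version__}

    # --- threshold trajectories (Df and lnDtf from one sweep per group) ---
    log.info("stage: threshold sweep (%d thresholds)", len(grid))
    try:
        df_a, ln_a, _ = _group_sweeps(images_a, grid, config, config.label_a)
        df_b, ln_b, _ = _group_sweeps(images_b, grid, config, config.label_b)
    except Exception as exc:
        raise RuntimeError(f"threshold sweep stage failed: {exc}") from exc

    trajectory_block = {}
    for stat in ("mean", "std"):
        c = optimal_threshold(df_a, df_b, stat, config.min_region_support)
        trajectory_block[f"{stat}_df"] = _contrast_dict(c)
    report["trajectory"] = {
        "curves": {config.label_a: _curve_dict(df_a),
                   config.label_b: _curve_dict(df_b)},
        "contrasts": trajectory_block,
    }

    transform_block = {}
    for stat in ("mean", "std"):
        c = optimal_threshold(ln_a, ln_b, stat, config.min_region_support)
        transform_block[f"{stat}_lndtf"] = _contrast_dict(c)
    # Gaussianity of lnDtf at the Mean(lnDtf) optimum
    t_opt = ThresholdSpec(transform_block["mean_lndtf"]["optimal_gray_level"])
    fits = {}
    for label, images in ((config.label_a, images_a), (config.label_b, images_b)):
        dfs = pooled_region_values(images, t_opt, config.region_size,
                                   config.box_sizes)
        dtf, _ = apply_transform(dfs)
        if dtf.size >= 20:
            g = gaussian_fit(np.log(dtf))
            fits[label] = {"mean": g.mean, "std": g.std,
                           "chi_square": g.chi_square, "score": g.score}
        else:
            fits[label] = None
    report["transform"] = {
        "curves": {config.label_a: _curve_dict(ln_a),
                   config.label_b: _curve_dict(ln_b)},
        "contrasts": transform_block,
        "gaussian_fit_at_mean_optimum": fits,
    }

    # --- multifractal spectra (group average of per-image spectra) ---
    log.info("stage: multifractal spectra")
    mf_block = {}
    for label, images in ((config.label_a, images_a), (config.label_b, images_b)):
        spectra = [spectrum(img, config.q_grid, config.eps_list) for img in images]
        params = spectrum_params(average_spectra(spectra))
        mf_block[label] = dataclasses.asdict(params)
    mf_block["delta_alpha_change"] = (mf_block[config.label_b]["delta_alpha"]
                                      - mf_block[config.label_a]["delta_alpha"])
    mf_block["delta_f_change"] = (mf_block[config.label_b]["delta_f"]
                                  - mf_block[config.label_a]["delta_f"])
    report["multifractal"] = mf_block

    # --- IPR scan ---
    log.info("stage: IPR scan (sizes %s)", list(config.ipr_sizes))
    ipr_block = {}
    scans = {}
    for label, images in ((config.label_a, images_a), (config.label_b, images_b)):
        scans[label] = ipr_scan(images, config.ipr_sizes)
        ipr_block[label] = {
            str(L): {"mean": r.mean, "std": r.std, "n_windows": r.n_windows}
            for L, r in scans[label].items()}
    changes = {}
    for L in scans[config.label_a]:
        if L in scans[config.label_b]:
            a, b = scans[config.label_a][L], scans[config.label_b][L]
            changes[str(L)] = {
                "mean_percent_change": 100.0 * (b.mean - a.mean) / a.mean,
                "std_percent_change": 100.0 * (b.std - a.std) / a.std
                if a.std > 0 else None,
            }
    ipr_block["percent_changes"] = changes
    report["ipr"] = ipr_block

    # --- headline percent-change table ---
    largest = max(int(k) for k in changes) if changes else None
    report["percent_change_table"] = {
        "MeanDf": trajectory_block["mean_df"]["percent_change"],
        "STDDf": trajectory_block["std_df"]["percent_change"],
        "Mean_lnDtf": transform_block["mean_lndtf"]["percent_change"],
        "STD_lnDtf": transform_block["std_lndtf"]["percent_change"],
        "Mean_IPR": changes[str(largest)]["mean_percent_change"] if largest else None,
    }

    if config.out_dir is not None:
        _emit(report, config, df_a, df_b, ln_a, ln_b, scans)
    return report


def _emit(report, config, df_a, df_b, ln_a, ln_b, scans) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    for name, curve in (("df_control", df_a), ("df_disease", df_b),
                        ("lndtf_control", ln_a), ("lndtf_disease", ln_b)):
        pd.DataFrame(_curve_dict(curve)).to_csv(out / f"curve_{name}.csv",
                                                index=False)
    rows = []
    for label, res in scans.items():
        for L, r in res.items():
            for v in r.window_values:
                rows.append({"group": label, "pixel_size": L, "ipr": v})
    pd.DataFrame(rows).to_csv(out / "ipr_windows.csv", index=False)
    if config.make_plots:
        _plots(report, out)


def _plots(report, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for block, fname, ylab in (("trajectory", "trajectory.png", "Df"),
                               ("transform", "lndtf_trajectory.png", "ln Dtf")):
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for label, curve in report[block]["curves"].items():
            x = curve["percents"]
            axes[0].plot(x, [np.nan if v is None else v for v in curve["mean"]],
                         marker="o", ms=3, label=label)
            axes[1].plot(x, [np.nan if v is None else v for v in curve["std"]],
                         marker="o", ms=3, label=label)
        for ax, stat in zip(axes, ("Mean", "STD")):
            ax.set_xlabel("threshold (% of full scale)")
            ax.set_ylabel(f"{stat}({ylab})")
            ax.legend()
        fig.tight_layout()
        fig.savefig(out / fname, dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, block in report["ipr"].items():
        if label == "percent_changes":
            continue
        sizes = sorted(int(k) for k in block)
        ax.plot(sizes, [block[str(L)]["mean"] for L in sizes], marker="s",
                label=label)
    ax.set_xlabel("IPR pixel size L")
    ax.set_ylabel("<IPR>")
    ax.set_xscale("log", base=2)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "ipr_vs_size.png", dpi=120)
    plt.close(fig)
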