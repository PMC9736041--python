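"""End-to-end orchestration: simulate → metrics → NTCP → compare → report.

Every output is regenerated from the inputs alone; a fixed seed gives
byte-identical CSVs.  The run manifest records the configuration, the seed
and package versions, and the per-stage log exposes how many patients the
exclusion rules silently removed from each table row.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

from . import __version__
from .compare import ComparisonResults, ModalityComparison
from .curves import PlanSet
from .dosimetry import metric_battery, records_to_frame
from .io import read_dvh_file, write_dvh_file
from .ntcp import load_lkb_registry, ntcp_battery, ntcp_records_to_frame
from .render import results_to_table
from .simulate import CohortConfig, default_config, generate_cohort

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

log = logging.getLogger("dvhcompare")

__all__ = ["RunConfig", "run_pipeline", "render_tables", "simulate_to_dir", "load_plans"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline run configuration.

    Either ``input_dir`` (directory of dialect DVH files) or a simulation
    seed/config is the plan source; outputs land under ``output_dir``.
    """

    output_dir: Path
    input_dir: Path | None = None
    seed: int = 0
    n_patients: int = 15
    params_path: Path | None = None
    make_plots: bool = True


def simulate_to_dir(config: CohortConfig, out_dir: Path) -> list[Path]:
    """Write one dialect DVH file per (patient, modality) plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for plan in generate_cohort(config):
        path = out_dir / f"{plan.patient_id}_{plan.modality}.dvh"
        write_dvh_file(plan, path)
        paths.append(path)
    manifest = {
        "n_patients": config.n_patients,
        "seed": config.seed,
        "prescription_Gy": config.prescription_dose,
        "n_fractions": config.n_fractions,
        "dose_per_fraction_Gy": config.dose_per_fraction,
        "files": [p.name for p in paths],
        "version": __version__,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return paths


def load_plans(input_dir: Path) -> list[PlanSet]:
    paths = sorted(Path(input_dir).glob("*.dvh"))
    if not paths:
        raise FileNotFoundError(f"no .dvh files under {input_dir}")
    return [read_dvh_file(p) for p in paths]


def _mean_curves_plot(plans: list[PlanSet], path: Path) -> None:
    """Per-structure mean cumulative DVH overlay for the three modalities."""
    structures = plans[0].structures
    modalities = sorted({p.modality for p in plans})
    ncol = 3
    nrow = int(np.ceil(len(structures) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    colors = {"helium": "tab:blue", "proton": "tab:red", "photon": "tab:green"}
    for ax, label in zip(axes.ravel(), structures):
        for mod in modalities:
            curves = [p[label].as_cumulative() for p in plans if p.modality == mod]
            grid = curves[0].dose_edges
            vols = np.mean(
                [np.interp(grid, c.dose_edges, c.volume) for c in curves], axis=0
            )
            ax.plot(grid, 100 * vols, label=mod, color=colors.get(mod))
        ax.set_title(label)
        ax.set_xlabel("dose [Gy]")
        ax.set_ylabel("volume [%]")
    axes.ravel()[0].legend()
    for ax in axes.ravel()[len(structures):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _ntcp_boxplot(ntcp_frame: pd.DataFrame, path: Path) -> None:
    """Per-endpoint NTCP boxplots with a ΔNTCP (He − H+) panel."""
    groups = list(ntcp_frame.groupby(["structure", "metric"]))
    fig, axes = plt.subplots(1, max(len(groups), 1), figsize=(3.2 * max(len(groups), 1), 3.6), squeeze=False)
    for ax, ((structure, endpoint), g) in zip(axes.ravel(), groups):
        wide = g.pivot_table(index="patient_id", columns="modality", values="value")
        cols = [c for c in ("helium", "proton", "photon") if c in wide.columns]
        data = [100 * wide[c] for c in cols]
        labels = list(cols)
        if {"helium", "proton"} <= set(wide.columns):
            data.append(100 * (wide["helium"] - wide["proton"]))
            labels.append("ΔHe−H+")
        ax.boxplot(data, tick_labels=labels)
        ax.axhline(0, lw=0.5, color="grey")
        ax.set_title(f"{structure}\n{endpoint}", fontsize=8)
        ax.set_ylabel("NTCP [%]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_tables(results: ComparisonResults, out_dir: Path, stem: str) -> dict[str, Path]:
    """Write the full-precision CSV and the rounded, annotated table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    full = out_dir / f"{stem}_comparison.csv"
    pretty = out_dir / f"{stem}_table.csv"
    results.frame.to_csv(full, index=False)
    results_to_table(results).to_csv(pretty, index=False)
    return {"full": full, "table": pretty}


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole pipeline; returns a bundle of output paths and results."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate/load"
    try:
        if config.input_dir is not None:
            plans = load_plans(config.input_dir)
        else:
            cohort_cfg = default_config(n_patients=config.n_patients, seed=config.seed)
            plans = generate_cohort(cohort_cfg)
        log.info("stage %s: %d plans", stage, len(plans))

        stage = "metrics"
        metric_records = [r for plan in plans for r in metric_battery(plan)]
        metrics_frame = records_to_frame(metric_records)
        metrics_path = out / "metrics.csv"
        metrics_frame.to_csv(metrics_path, index=False)
        log.info("stage %s: %d records", stage, len(metric_records))

        stage = "ntcp"
        registry = load_lkb_registry(config.params_path)
        ntcp_records = [r for plan in plans for r in ntcp_battery(plan, registry)]
        ntcp_frame = ntcp_records_to_frame(ntcp_records)
        ntcp_path = out / "ntcp.csv"
        ntcp_frame.to_csv(ntcp_path, index=False)
        log.info("stage %s: %d records", stage, len(ntcp_records))

        stage = "compare"
        dose_results = ModalityComparison.from_metric_records(metric_records).fit()
        ntcp_results = ModalityComparison.from_ntcp_records(ntcp_records).fit()
        tables = {}
        tables.update(
            {f"dose_{k}": v for k, v in render_tables(dose_results, out / "tables", "dose").items()}
        )
        tables.update(
            {f"ntcp_{k}": v for k, v in render_tables(ntcp_results, out / "tables", "ntcp").items()}
        )
        for r in dose_results.rows:
            if r.n_excluded:
                log.info(
                    "exclusion: %s %s dropped %d/%d patients (row n/a: %s)",
                    r.structure, r.metric, r.n_excluded, r.n_patients, r.excluded_row,
                )

        stage = "plots"
        plot_paths = {}
        if config.make_plots:
            dvh_plot = out / "dvh_overlay.png"
            _mean_curves_plot(plans, dvh_plot)
            ntcp_plot = out / "ntcp_boxplots.png"
            _ntcp_boxplot(
                ntcp_records_to_frame(ntcp_records)
                .rename(columns={"endpoint": "metric", "ntcp": "value"}),
                ntcp_plot,
            )
            plot_paths = {"dvh_overlay": dvh_plot, "ntcp_boxplots": ntcp_plot}

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "n_patients": config.n_patients,
            "input_dir": str(config.input_dir) if config.input_dir else None,
            "version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "outputs": {
                "metrics": metrics_path.name,
                "ntcp": ntcp_path.name,
                **{k: str(v.relative_to(out)) for k, v in tables.items()},
                **{k: v.name for k, v in plot_paths.items()},
            },
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "plans": plans,
        "metrics": metrics_frame,
        "ntcp": ntcp_frame,
        "dose_results": dose_results,
        "ntcp_results": ntcp_results,
        "paths": {"metrics": metrics_path, "ntcp": ntcp_path, "manifest": manifest_path, **tables, **plot_paths},
    }
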