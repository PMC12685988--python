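"""End-to-end orchestration: simulate or ingest, analyze, classify, summarize.

Every constant of the analysis (preload threshold, grid increment, stiffness
levels, classifier thresholds, CT threshold, quantile convention) lives in
:class:`RunConfig`, which is echoed into every results directory so a run
can be reproduced from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import AREA_RATIO_THRESHOLD, SLOPE_WINDOW, classify
from .errors import InsufficientStrainError, NoduleMechError
from .io import (
    read_load_test,
    read_nodule_table,
    write_nodule_table,
    write_recording,
    write_results,
)
from .mechanics import (
    DEFAULT_LEVELS,
    resample_to_grid,
    stiffness_profile,
    to_stress_strain,
)
from .ct import CALCIUM_THRESHOLD_HU
from .stats import (
    compare_groups,
    correlate_with_ct,
    stiffness_summary,
    stress_quartile_table,
)
from .synthetic import CohortSpec, simulate_cohort
from .types import PRELOAD_THRESHOLD, MachineSpec, NoduleRecord, TestRecording


@dataclass
class RunConfig:
    """All tunables of an analysis run, with study defaults."""

    mode: str = "simulate"  # "simulate" or "ingest"
    out_dir: str = "results"
    seed: int = 0
    # simulate mode
    n_nodules: int = 129
    # ingest mode
    recordings_dir: str | None = None
    nodule_table: str | None = None
    # machine
    machine: MachineSpec = field(default_factory=MachineSpec)
    # analysis constants
    preload_threshold: float = PRELOAD_THRESHOLD  # N/mm^2
    grid_increment: float = 0.05
    levels: tuple[float, ...] = DEFAULT_LEVELS
    area_ratio_threshold: float = AREA_RATIO_THRESHOLD
    slope_window: tuple[float, float] = SLOPE_WINDOW
    ct_threshold_hu: float = CALCIUM_THRESHOLD_HU
    quantile_convention: str = "linear"
    table_max_strain: float = 0.70
    # outputs
    figures: bool = True
    write_recordings: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise NoduleMechError(f"unknown run mode {self.mode!r}")
        if self.grid_increment <= 0 or self.preload_threshold <= 0:
            raise NoduleMechError("thresholds and increments must be positive")
        for level in self.levels:
            ratio = level / self.grid_increment
            if abs(ratio - round(ratio)) > 1e-9:
                raise NoduleMechError(
                    f"stiffness level {level} is not a multiple of the grid "
                    f"increment {self.grid_increment}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "machine" in raw and isinstance(raw["machine"], dict):
            raw["machine"] = MachineSpec(**raw["machine"])
        for key in ("levels", "slope_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["machine"] = dataclasses.asdict(self.machine)
        return d


def analyze_cohort(
    records: Sequence[NoduleRecord],
    recordings: Sequence[TestRecording],
    config: RunConfig,
):
    """Run mechanics + classification over a cohort.

    Returns (profiles, gridded_curves).  Any stage failure is re-raised with
    the stage name and nodule id attached.
    """
    profiles, gridded = [], []
    for record, rec in zip(records, recordings):
        stage = "stress_strain"
        try:
            curve = to_stress_strain(rec, record, config.preload_threshold)
            stage = "resample"
            grid_curve = resample_to_grid(curve, config.grid_increment)
            stage = "stiffness"
            profile = stiffness_profile(curve, config.levels)
            stage = "classify"
            try:
                result = classify(
                    grid_curve,
                    area_threshold=config.area_ratio_threshold,
                    baseline=config.preload_threshold,
                    window=config.slope_window,
                )
                profile.pattern = result.label
            except InsufficientStrainError:
                profile.pattern = None  # unclassifiable: test ended early
        except NoduleMechError as exc:
            raise NoduleMechError(
                f"stage '{stage}' failed for nodule '{record.nodule_id}': {exc}"
            ) from exc
        profiles.append(profile)
        gridded.append(grid_curve)
    return profiles, gridded


def run(config: RunConfig) -> Path:
    """Execute a full run and return the results directory.

    Layout: results.csv (per-nodule), quartile_table.csv, summaries.csv,
    correlations.csv, comparisons.csv, nodules.csv, figures/ (optional),
    run.json (config echo, seed, version).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mode == "simulate":
        spec = CohortSpec(
            n_nodules=config.n_nodules, machine=config.machine, seed=config.seed
        )
        records, recordings = simulate_cohort(spec)
        if config.write_recordings:
            rec_dir = out / "recordings"
            rec_dir.mkdir(exist_ok=True)
            for rec in recordings:
                write_recording(rec, rec_dir / f"{rec.nodule_id}.csv")
    else:
        if not config.recordings_dir or not config.nodule_table:
            raise NoduleMechError(
                "ingest mode requires recordings_dir and nodule_table"
            )
        records = read_nodule_table(config.nodule_table)
        recordings = [
            read_load_test(
                Path(config.recordings_dir) / f"{r.nodule_id}.csv",
                config.machine,
                nodule_id=r.nodule_id,
            )
            for r in records
        ]

    profiles, gridded = analyze_cohort(records, recordings, config)

    write_nodule_table(records, out / "nodules.csv")
    results = write_results(profiles, records, out / "results.csv")

    table = stress_quartile_table(
        gridded, config.grid_increment, config.table_max_strain
    )
    table.to_csv(out / "quartile_table.csv", float_format="%.12g")

    stiffness_summary(profiles).to_csv(out / "summaries.csv", index=False)

    if results["ct_hu"].notna().sum() >= 3:
        correlate_with_ct(results).to_csv(out / "correlations.csv", index=False)

    comparisons = _group_comparisons(results)
    if comparisons is not None:
        comparisons.to_csv(out / "comparisons.csv", index=False)

    if config.figures:
        from . import plots

        fig_dir = out / "figures"
        fig_dir.mkdir(exist_ok=True)
        plots.quartile_band_plot(table, fig_dir / "stress_quartiles.svg")
        plots.stiffness_boxplots(results, fig_dir / "cs_ce_boxplots.svg")
        if results["ct_hu"].notna().sum() >= 3:
            plots.ct_scatter(results, fig_dir / "ct_scatter.svg")

    (out / "run.json").write_text(
        json.dumps(
            {
                "package": "nodulemech",
                "version": __version__,
                "seed": config.seed,
                "n_nodules": len(records),
                "config": config.to_dict(),
            },
            indent=2,
            default=str,
        )
    )
    return out


def _group_comparisons(results: pd.DataFrame) -> pd.DataFrame | None:
    """Dialysis-by-pattern contingency contrast, when both are available."""
    if "dialysis" not in results or results["dialysis"].isna().all():
        return None
    mask = results["pattern"].notna() & results["dialysis"].notna()
    sub = results[mask]
    if sub["pattern"].nunique() != 2:
        return None
    cmp = compare_groups(
        sub["pattern"].to_numpy(), sub["dialysis"].astype(bool).to_numpy()
    )
    groups = list(cmp.group_summaries)
    return pd.DataFrame(
        [
            {
                "contrast": "dialysis_by_pattern",
                "test": cmp.test,
                "p_value": cmp.p_value,
                "group_a": groups[0],
                "share_a": cmp.group_summaries[groups[0]],
                "group_b": groups[1],
                "share_b": cmp.group_summaries[groups[1]],
                "table": json.dumps(cmp.table),
            }
        ]
    )
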