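"""End-to-end synthetic scratch-assay experiments.

One config describes a control/treated comparison: per condition a
Fisher–KPP simulation of the closing wound, per replicate a rendered
time-lapse stack (replicates differ in imaging noise and growth-count
noise, as fields of view of the same biology), then segmentation, closure
and doubling-time fits, the algebraic motility estimate, and replicate
statistics.  All randomness flows from one root seed through
``numpy.random.SeedSequence`` spawning, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .growth import simulate_growth_curve
from .kinetics import (
    LN2,
    estimate_motility,
    fit_closure_velocity,
    fit_doubling_time,
)
from .render import RenderConfig, render_timelapse
from .segmentation import (
    SegmentationConfig,
    initial_wound_width,
    measure_area_series,
    segment_wound,
)
from .simulate import FKParameters, Grid1D, make_scratch_initial_condition, simulate_fk_1d
from .stack import write_stack
from .stats import paired_t_test, summarize, treatment_ratio

__all__ = ["ConditionSpec", "ExperimentConfig", "PipelineStageError", "run_synthetic_experiment"]

log = logging.getLogger("woundkinetics")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage label."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition (e.g. control or treated monolayer)."""

    label: str
    D: float  # random motility coefficient, µm²/h
    tau: float  # doubling time, h
    n0: float = 9e3  # initial cell count for the growth curve
    growth_noise_cv: float = 0.05


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of a synthetic control-vs-treated experiment.

    Defaults emulate the study protocol: a ~800 µm scratch in a confluent
    keratinocyte monolayer imaged every 15 min for 18 h, three replicate
    fields per condition, and a treated condition whose motility is
    3.24× the control with unchanged doubling time.
    """

    conditions: tuple[ConditionSpec, ...] = (
        ConditionSpec(label="control", D=600.0, tau=24.0),
        ConditionSpec(label="treated", D=1944.0, tau=24.0),
    )
    u_hat: float = 1.2e-3  # confluent density, cells/µm²
    b: float = 1200.0  # initial wound width, µm (wide enough that the two
    # edges stay independent over the 18 h record — the v = alpha*b/2
    # geometry assumes non-interacting fronts)
    x_min: float = 0.0
    x_max: float = 4000.0
    n_nodes: int = 801
    dt: float = 0.005  # h
    t_end: float = 18.0  # h
    frame_interval: float = 0.25  # h (15 min)
    pixel_size: float = 5.0  # µm/px
    frame_rows: int = 200
    noise_sd: float = 0.05
    cell_texture_amplitude: float = 0.3
    background_level: float = 0.5
    growth_times: tuple[float, ...] = (0.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0)
    n_replicates: int = 3
    seed: int = 0
    write_images: bool = True
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)

    @property
    def grid(self) -> Grid1D:
        return Grid1D(
            x_min=self.x_min, x_max=self.x_max, n_nodes=self.n_nodes,
            dt=self.dt, t_end=self.t_end,
        )

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(0.0, self.t_end + 1e-9, self.frame_interval)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = [dataclasses.asdict(c) for c in self.conditions]
        d["segmentation"] = dataclasses.asdict(self.segmentation)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["conditions"] = tuple(ConditionSpec(**c) for c in d.get("conditions", []))
        if "segmentation" in d:
            d["segmentation"] = SegmentationConfig(**d["segmentation"])
        if "growth_times" in d:
            d["growth_times"] = tuple(d["growth_times"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
                if not isinstance(exc, PipelineStageError):
                    raise PipelineStageError(name, exc) from exc
                return False
            log.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def run_synthetic_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run simulate → render → segment → fit → compare and write all outputs.

    Writes per-replicate area series (CSV), per-replicate fits (JSON),
    condition summaries (CSV), pairwise comparisons against the first
    condition (JSON) and a markdown report under ``out_dir``.  Returns the
    report as a dict.  Any stage failure raises
    :class:`PipelineStageError` with the stage label; outputs of completed
    stages are left on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # one noise stream per replicate, shared across conditions: replicates are
    # paired (same-day fields), so identical conditions give identical fits
    root_ss = np.random.SeedSequence(config.seed)
    replicate_seeds = [tuple(ss.spawn(2)) for ss in root_ss.spawn(config.n_replicates)]
    grid = config.grid

    records: list[dict] = []
    for ci, cond in enumerate(config.conditions):
        params = FKParameters(D=cond.D, k=LN2 / cond.tau, u_hat=config.u_hat, b=config.b)
        with _stage(f"simulate[{cond.label}]"):
            init = make_scratch_initial_condition(params, grid)
            field_ = simulate_fk_1d(init, params, grid, save_times=config.frame_times)

        for ri in range(config.n_replicates):
            render_ss, growth_ss = replicate_seeds[ri]
            cfg = RenderConfig(
                pixel_size=config.pixel_size,
                frame_shape=(config.frame_rows, int(round(grid.length / config.pixel_size))),
                cell_texture_amplitude=config.cell_texture_amplitude,
                background_level=config.background_level,
                noise_sd=config.noise_sd,
                seed=_seed_int(render_ss),
            )
            with _stage(f"render[{cond.label}/{ri}]"):
                stack, gt_masks = render_timelapse(field_, cfg, u_hat=config.u_hat)
                if config.write_images:
                    write_stack(
                        out / f"stack_{cond.label}_{ri}.tif",
                        stack,
                        metadata={
                            "condition": cond.label,
                            "replicate": ri,
                            "D_true": cond.D,
                            "tau_true": cond.tau,
                            "b_true": config.b,
                            "seed": cfg.seed,
                        },
                    )
            with _stage(f"segment[{cond.label}/{ri}]"):
                series = measure_area_series(stack, config.segmentation)
                series.to_csv(out / f"series_{cond.label}_{ri}.csv")
                mask0 = segment_wound(stack.frames[0], config.segmentation)
                b_hat = initial_wound_width(mask0, stack.pixel_size)
            with _stage(f"fit[{cond.label}/{ri}]"):
                closure = fit_closure_velocity(series)
                growth = simulate_growth_curve(
                    cond.n0, cond.tau, np.asarray(config.growth_times),
                    noise_cv=cond.growth_noise_cv, seed=_seed_int(growth_ss),
                )
                logi = fit_doubling_time(growth)
                mot = estimate_motility(closure.alpha, b_hat, logi.tau)
            records.append(
                {
                    "condition": cond.label,
                    "replicate": ri,
                    "alpha_per_h": closure.alpha,
                    "t_lag_h": closure.t_lag,
                    "r_squared": closure.r_squared,
                    "no_closure": closure.no_closure,
                    "b_hat_um": b_hat,
                    "tau_h": logi.tau,
                    "v_um_per_h": mot.v,
                    "k_per_h": mot.k,
                    "D_um2_per_h": mot.D,
                    "phi": mot.phi,
                }
            )

    with _stage("compare"):
        fits = pd.DataFrame.from_records(records)
        fits.to_csv(out / "fits.csv", index=False)
        (out / "fits.json").write_text(json.dumps(records, indent=2, sort_keys=True))

        summaries = []
        by_cond: dict[str, pd.DataFrame] = {
            c.label: fits[fits["condition"] == c.label] for c in config.conditions
        }
        for label, sub in by_cond.items():
            for stat in ("alpha_per_h", "tau_h", "D_um2_per_h"):
                s = summarize(sub[stat].to_numpy(), label=label, statistic=stat)
                summaries.append(
                    {"condition": label, "statistic": stat, "mean": s.mean, "sem": s.sem, "n": s.n}
                )
        pd.DataFrame(summaries).to_csv(out / "summary.csv", index=False)

        control_label = config.conditions[0].label
        comparisons = {}
        for cond in config.conditions[1:]:
            comp = {}
            for stat in ("alpha_per_h", "tau_h", "D_um2_per_h"):
                a = by_cond[cond.label][stat].to_numpy()
                c = by_cond[control_label][stat].to_numpy()
                tt = paired_t_test(a, c)
                comp[stat] = {
                    "ratio": treatment_ratio(float(a.mean()), float(c.mean())),
                    "p_value": tt.p_value,
                    "degenerate": tt.degenerate,
                }
            comparisons[f"{cond.label}_vs_{control_label}"] = comp
        (out / "comparisons.json").write_text(json.dumps(comparisons, indent=2, sort_keys=True))

    report = {
        "config": config.to_dict(),
        "fits": records,
        "summaries": summaries,
        "comparisons": comparisons,
    }
    _write_report_md(out / "report.md", report)
    return report


def _write_report_md(path: Path, report: dict) -> None:
    lines = ["# Synthetic scratch-assay experiment", ""]
    lines.append("## Per-replicate fits")
    lines.append("")
    lines.append("| condition | rep | alpha (1/h) | t_lag (h) | tau (h) | D (µm²/h) | phi |")
    lines.append("|---|---|---|---|---|---|---|")
    for r in report["fits"]:
        lines.append(
            f"| {r['condition']} | {r['replicate']} | {r['alpha_per_h']:.4f} "
            f"| {r['t_lag_h']:.2f} | {r['tau_h']:.2f} | {r['D_um2_per_h']:.1f} "
            f"| {r['phi']:.3f} |"
        )
    lines.append("")
    lines.append("## Comparisons (vs first condition)")
    lines.append("")
    for name, comp in report["comparisons"].items():
        for stat, c in comp.items():
            flag = " (degenerate)" if c["degenerate"] else ""
            lines.append(f"- {name} / {stat}: ratio = {c['ratio']:.3f}, p = {c['p_value']:.3g}{flag}")
    path.write_text("\n".join(lines) + "\n")
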