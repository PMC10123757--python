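"""End-to-end orchestration: record -> cycles -> metrics -> envelope -> trends.

`analyze_curve` / `analyze_record` are the in-memory entry points; the
`run_analysis` / `run_report` wrappers add file I/O and are what the CLI
calls.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .envelope import AlphaStarResult, EnvelopeCurve, alpha_star, envelope_curve, work_to_fracture
from .errors import SegmentationError, SilkmechError
from .kinematics import TrueCurve, engineering_from_record, true_from_engineering
from .metrics import (
    absorbed_energy,
    dissipated_energy,
    elastic_modulus,
    recovered_energy,
    yield_stress,
)
from .records import (
    RESULTS_COLUMNS,
    FiberGeometry,
    ResultsTable,
    read_geometry,
    read_tensile_record,
    write_results,
)
from .segmentation import Cycle, default_onset_threshold, segment_cycles
from .trends import TrendFit, endpoint_summary, linear_trend

__all__ = ["AnalysisConfig", "AnalysisResult", "analyze_curve", "analyze_record", "run_analysis", "run_report"]

log = logging.getLogger("silkmech")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline."""

    onset_threshold_abs: float = 0.5     # MPa
    onset_threshold_rel: float = 0.01    # fraction of the global stress maximum
    modulus_window: float = 0.01         # strain span of the initial-slope fit
    yield_fraction: float = 0.95         # proportional-limit line slope fraction
    slope_tolerance: float = 0.20        # alpha* slope-agreement tolerance
    min_points: int = 10                 # minimum samples per branch
    use_time_gaps: bool = False          # alternate cycle-boundary cue
    embed_branches: bool = False         # include per-cycle branches in the bundle
    delimiter: str = ","
    columns: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.yield_fraction < 1.0:
            raise SilkmechError("yield_fraction must lie in (0, 1)")
        if not 0.0 < self.slope_tolerance < 1.0:
            raise SilkmechError("slope_tolerance must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnalysisResult:
    """Bundle produced by a full pipeline run."""

    table: ResultsTable
    cycles: list[Cycle]
    envelope: EnvelopeCurve | None
    work_to_fracture: float | None
    fit_modulus: TrendFit | None
    fit_yield: TrendFit | None
    endpoints: dict
    alpha: AlphaStarResult | None = None
    onset_threshold: float = 0.0

    def summary(self) -> dict:
        out = {
            "n_cycles": len(self.table),
            "onset_threshold_MPa": self.onset_threshold,
            "work_to_fracture_MJm3": self.work_to_fracture,
            "endpoints": self.endpoints,
        }
        if self.fit_modulus is not None:
            out["modulus_trend"] = asdict(self.fit_modulus)
        if self.fit_yield is not None:
            out["yield_trend"] = asdict(self.fit_yield)
        if self.alpha is not None:
            out["alpha_star"] = asdict(self.alpha)
        return out


def analyze_curve(curve: TrueCurve, config: AnalysisConfig | None = None,
                  reference: TrueCurve | None = None) -> AnalysisResult:
    """Run segmentation, per-cycle metrics, envelope and trends on a true curve."""
    cfg = config or AnalysisConfig()
    thr = default_onset_threshold(curve.stress, cfg.onset_threshold_abs, cfg.onset_threshold_rel)

    t0 = _time.perf_counter()
    cycles = segment_cycles(curve, thr, cfg.min_points, use_time_gaps=cfg.use_time_gaps)
    log.info("segmented %d cycles in %.2f s", len(cycles), _time.perf_counter() - t0)

    rows = []
    prev_complete: Cycle | None = None
    for c in cycles:
        row = {
            "cycle": c.index,
            "eps_init": c.eps_init,
            "eps_max": c.eps_max,
            "sigma_max_MPa": c.sigma_max,
            "complete": c.complete,
            "modulus_MPa": np.nan,
            "fit_r2": np.nan,
            "yield_MPa": np.nan,
            "yield_strain": np.nan,
            "absorbed_MJm3": np.nan,
            "dissipated_MJm3": np.nan,
            "recovered_MJm3": np.nan,
            "concur": False,
        }
        if len(c.loading) >= cfg.min_points:
            try:
                e_mod, r2 = elastic_modulus(c.loading, cfg.modulus_window, onset_threshold=thr)
                row["modulus_MPa"], row["fit_r2"] = e_mod, r2
                yld = yield_stress(c.loading, e_mod, eps_init=c.eps_init, fraction=cfg.yield_fraction)
                if yld is not None:
                    row["yield_MPa"], row["yield_strain"] = yld
            except SilkmechError as exc:
                log.warning("cycle %d: %s", c.index, exc)
            row["absorbed_MJm3"] = absorbed_energy(c.loading)
            w_dis = dissipated_energy(c)
            if w_dis is not None:
                row["dissipated_MJm3"] = w_dis
            if prev_complete is not None:
                rec = recovered_energy(prev_complete, c)
                row["recovered_MJm3"], row["concur"] = rec.value, rec.concur
        if c.complete:
            prev_complete = c
        rows.append(row)

    table = ResultsTable(pd.DataFrame(rows, columns=RESULTS_COLUMNS)) if rows else ResultsTable()

    env = wf = None
    complete = [c for c in cycles if c.complete]
    if complete:
        env = envelope_curve(complete)
        wf = work_to_fracture(env)

    fit_e = fit_y = None
    endpoints: dict = {}
    if len(table):
        df = table.frame
        ok_e = df["modulus_MPa"].notna()
        if ok_e.sum() >= 2 and df.loc[ok_e, "eps_init"].nunique() > 1:
            fit_e = linear_trend(df.loc[ok_e, "eps_init"], df.loc[ok_e, "modulus_MPa"])
        ok_y = df["yield_MPa"].notna()
        if ok_y.sum() >= 2 and df.loc[ok_y, "eps_init"].nunique() > 1:
            fit_y = linear_trend(df.loc[ok_y, "eps_init"], df.loc[ok_y, "yield_MPa"])
        endpoints = endpoint_summary(table, fit_e, fit_y)

    alpha = None
    if reference is not None and env is not None:
        alpha = alpha_star(TrueCurve(env.strain, env.stress), reference, cfg.slope_tolerance)

    return AnalysisResult(
        table=table, cycles=cycles, envelope=env, work_to_fracture=wf,
        fit_modulus=fit_e, fit_yield=fit_y, endpoints=endpoints,
        alpha=alpha, onset_threshold=thr,
    )


def analyze_record(record, geometry: FiberGeometry, config: AnalysisConfig | None = None,
                   reference: TrueCurve | None = None) -> AnalysisResult:
    """Convert a machine record to true coordinates and analyze it."""
    eng = engineering_from_record(record, geometry)
    return analyze_curve(true_from_engineering(eng), config, reference)


def run_analysis(record_path, geometry_path, config: AnalysisConfig | None = None,
                 out_dir=None, reference_path=None) -> AnalysisResult:
    """File-level pipeline: read inputs, analyze, optionally write the bundle."""
    cfg = config or AnalysisConfig()
    record = read_tensile_record(record_path, delimiter=cfg.delimiter, columns=cfg.columns or None)
    geometry = read_geometry(geometry_path)
    reference = None
    if reference_path is not None:
        ref_df = pd.read_csv(reference_path, sep=cfg.delimiter)
        reference = TrueCurve(ref_df.iloc[:, 0].to_numpy(), ref_df.iloc[:, 1].to_numpy())
    result = analyze_record(record, geometry, cfg, reference)
    if not result.cycles:
        raise SegmentationError(f"no loading-unloading cycles detected in {record_path}")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_results(result.table, out_dir / "cycle_metrics.csv", delimiter=cfg.delimiter)
        if result.envelope is not None:
            pd.DataFrame({"strain": result.envelope.strain, "stress_MPa": result.envelope.stress}).to_csv(
                out_dir / "envelope.csv", sep=cfg.delimiter, index=False, float_format="%.12g"
            )
        bundle = {"config": cfg.to_dict(), **result.summary()}
        if cfg.embed_branches:
            bundle["cycles"] = [
                {
                    "index": c.index,
                    "loading": {"strain": c.loading.strain, "stress_MPa": c.loading.stress},
                    "unloading": {"strain": c.unloading.strain, "stress_MPa": c.unloading.stress},
                }
                for c in result.cycles
            ]
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(bundle, fh, indent=1, default=_json_default)
    return result


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_report(results_path, out_dir) -> list[Path]:
    """Charts and a text summary from a written cycle-metrics table.

    Emits modulus-vs-onset, yield-vs-onset and energies-vs-maximum-strain
    charts plus ``report.txt``; the yield chart is skipped (with a notice)
    when no cycle yielded.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = ResultsTable.read(results_path)
    df = table.frame
    if df.empty:
        raise SilkmechError("results table is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    fit_e = fit_y = None
    ok_e = df["modulus_MPa"].notna()
    if ok_e.sum() >= 2:
        fit_e = linear_trend(df.loc[ok_e, "eps_init"], df.loc[ok_e, "modulus_MPa"])
    ok_y = df["yield_MPa"].notna()
    if ok_y.sum() >= 2:
        fit_y = linear_trend(df.loc[ok_y, "eps_init"], df.loc[ok_y, "yield_MPa"])

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(df.loc[ok_e, "eps_init"], df.loc[ok_e, "modulus_MPa"] / 1000.0, "kd")
    if fit_e is not None:
        xs = np.linspace(df["eps_init"].min(), df["eps_init"].max(), 50)
        ax.plot(xs, (fit_e.slope * xs + fit_e.intercept) / 1000.0, "k--")
    ax.set_xlabel("onset true strain")
    ax.set_ylabel("elastic modulus (GPa)")
    fig.tight_layout()
    p = out_dir / "modulus_vs_onset.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    if ok_y.any():
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(df.loc[ok_y, "eps_init"], df.loc[ok_y, "yield_MPa"], "ks")
        if fit_y is not None:
            xs = np.linspace(df.loc[ok_y, "eps_init"].min(), df.loc[ok_y, "eps_init"].max(), 50)
            ax.plot(xs, fit_y.slope * xs + fit_y.intercept, "k--")
        ax.set_xlabel("onset true strain")
        ax.set_ylabel("yield stress (MPa)")
        fig.tight_layout()
        p = out_dir / "yield_vs_onset.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        log.warning("no yield values in the table; yield chart skipped")

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(df["eps_max"], df["absorbed_MJm3"], "kd", label="absorbed")
    ax.plot(df["eps_max"], df["dissipated_MJm3"], "rs", mfc="none", label="dissipated")
    ax.set_xlabel("maximum true strain of the cycle")
    ax.set_ylabel("energy density (MJ/m$^3$)")
    ax.legend()
    fig.tight_layout()
    p = out_dir / "energies_vs_strain.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    summary = endpoint_summary(table, fit_e, fit_y)
    lines = [f"cycles analysed: {len(df)}"]
    for key, val in summary.items():
        lines.append(f"{key}: {val}")
    p = out_dir / "report.txt"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)
    return written
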