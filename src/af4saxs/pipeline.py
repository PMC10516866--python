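"""End-to-end pipeline: simulate -> process -> bragg/mals -> quantify.

Each stage reads its inputs from, and writes its outputs to, a run
directory, so any stage can be rerun in isolation on cached upstream
outputs with an identical result.  Every output table carries a
provenance header (resolved-config hash, seed, stage name) and runs are
byte-identical for the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bragg import bragg_series
from .io import (Fractogram, load_formulation,
                 read_fractogram, write_fractogram)
from .mals import mals_series
from .processing import (elution_trace, peak_frames, select_buffer_frames,
                         subtract_buffer)
from .quantify import (c_lpx_total, derive_stoichiometry, distribution_summaries,
                       free_rna_from_uv, normalize_bragg_area, rebin_by_rg,
                       size_resolved_table)
from .synth import reference_scenario

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Raised with the failing stage's name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Fully-serializable run configuration (defaults reproduce the
    reference two-population scenario end to end)."""

    seed: int = 0
    scenario: str = "reference"            # simulate stage scenario
    noise_scale: float = 0.01
    stages: tuple[str, ...] = ("simulate", "process", "bragg", "mals", "quantify")
    input_dir: str | None = None            # read instead of simulating
    buffer_window: str | tuple[int, int] = "auto"
    rna_time_window: tuple[float, float] = (10.0, 25.0)
    lpx_time_window: tuple[float, float] = (26.0, 62.0)
    rna_threshold: float = 0.02
    lpx_threshold: float = 0.02
    bragg_window: tuple[float, float] = (0.7, 1.4)
    bragg_baseline: str = "power_law"
    epsilon_rna: float = 0.025              # mL ug^-1 cm^-1
    uv_path_cm: float = 1.0
    flow_calibration: float = 1.0
    rg_extrapolation_degree: int = 2
    n_rg_bins: int = 10
    formulation: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        return cfg

    def resolved(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d

    def digest(self) -> str:
        # hash the scientific parameters; which stages run is execution
        # detail, so cached-stage reruns keep the same provenance hash
        d = self.resolved()
        d.pop("stages", None)
        blob = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(cfg: RunConfig, stage: str) -> str:
    return (f"# af4saxs run: stage={stage} config_hash={cfg.digest()} "
            f"seed={cfg.seed} version={__version__}\n")


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, stage: str):
    with open(path, "w") as fh:
        fh.write(_header(cfg, stage))
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute the enabled stages into ``out_dir``; returns the run dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(cfg.stages)
    known = ("simulate", "process", "bragg", "mals", "quantify")
    for st in stages:
        if st not in known:
            raise PipelineError(st, f"unknown stage (choose from {known})")
    if "quantify" in stages:
        for dep in ("bragg", "mals"):
            if dep not in stages and not (out / f"{dep}_series.csv").exists():
                raise PipelineError(
                    "quantify", f"requires the '{dep}' stage or its cached output"
                )

    if "simulate" in stages:
        _stage_simulate(cfg, out)
    if "process" in stages:
        _stage_process(cfg, out)
    if "bragg" in stages:
        _stage_bragg(cfg, out)
    if "mals" in stages:
        _stage_mals(cfg, out)
    if "quantify" in stages:
        _stage_quantify(cfg, out)
    return out


def _load_fractogram(cfg: RunConfig, out: Path, subtracted: bool = False) -> Fractogram:
    sub = out / "subtracted"
    raw = Path(cfg.input_dir) if cfg.input_dir else out / "fractogram"
    d = sub if (subtracted and (sub / "manifest.csv").exists()) else raw
    if not (d / "manifest.csv").exists():
        raise PipelineError("io", f"no fractogram at {d}")
    mals_path = d / "mals.csv"
    return read_fractogram(d, d / "manifest.csv",
                           mals_path if mals_path.exists() else None)


def _stage_simulate(cfg: RunConfig, out: Path):
    if cfg.scenario != "reference":
        raise PipelineError("simulate", f"unknown scenario {cfg.scenario!r}")
    fr, gt = reference_scenario(noise_seed=cfg.seed, noise_scale=cfg.noise_scale)
    write_fractogram(fr, out / "fractogram")
    ilpx = gt.population_index("sphere_lamellar")
    truth = pd.DataFrame({
        "time_min": gt.frame_times,
        "kc": gt.kc,
        "uv_true": gt.uv_true,
        **{f"conc_{p.kind}": gt.conc[i] for i, p in enumerate(gt.populations)},
        **{f"rg_{p.kind}": gt.rg[i] for i, p in enumerate(gt.populations)},
        "bragg_area_true": gt.bragg_area[ilpx],
    })
    _write_table(truth, out / "ground_truth.csv", cfg, "simulate")


def _stage_process(cfg: RunConfig, out: Path):
    fr = _load_fractogram(cfg, out)
    try:
        buf = select_buffer_frames(fr, cfg.buffer_window)
    except ValueError as exc:
        raise PipelineError("process", str(exc)) from exc
    fr2 = subtract_buffer(fr, buf)
    write_fractogram(fr2, out / "subtracted")
    traces = pd.DataFrame({
        "time_min": fr2.frame_times,
        "uv": elution_trace(fr2, "uv").values,
        "saxs_integrated": elution_trace(fr2, "saxs_integrated").values,
        "ls90": (elution_trace(fr2, "ls90").values if fr2.mals
                 else np.full(fr2.n_frames, np.nan)),
    })
    _write_table(traces, out / "traces.csv", cfg, "process")


def _stage_bragg(cfg: RunConfig, out: Path):
    fr = _load_fractogram(cfg, out, subtracted=True)
    traces = _read_table(out / "traces.csv")
    sax = elution_trace(fr, "saxs_integrated")
    idx = peak_frames(sax, cfg.lpx_threshold, time_window=cfg.lpx_time_window)
    try:
        table, _area = bragg_series(fr, idx, window=tuple(cfg.bragg_window),
                                    baseline=cfg.bragg_baseline)
    except Exception as exc:
        raise PipelineError("bragg", str(exc)) from exc
    table = table.reset_index()
    _write_table(table, out / "bragg_series.csv", cfg, "bragg")


def _stage_mals(cfg: RunConfig, out: Path):
    fr = _load_fractogram(cfg, out, subtracted=True)
    gt_path = out / "ground_truth.csv"
    if gt_path.exists():
        kc = _read_table(gt_path)["kc"].to_numpy()
    else:
        # Kc = K c(t); without a calibrated K the MW column is in
        # arbitrary units while Rg is unaffected (Kc-scale-free)
        kc = np.ones(fr.n_frames)
    try:
        table = mals_series(fr, kc)
    except Exception as exc:
        raise PipelineError("mals", str(exc)) from exc
    _write_table(table, out / "mals_series.csv", cfg, "mals")


def _stage_quantify(cfg: RunConfig, out: Path):
    from .mals import extrapolate_rg
    from .processing import ElutionTrace

    traces = _read_table(out / "traces.csv")
    t = traces["time_min"].to_numpy()
    uv = ElutionTrace(t, traces["uv"].to_numpy(), "uv")
    sax = ElutionTrace(t, traces["saxs_integrated"].to_numpy(), "saxs_integrated")
    p = load_formulation(**cfg.formulation)
    s = derive_stoichiometry(p)
    rna_idx = peak_frames(uv, cfg.rna_threshold, time_window=cfg.rna_time_window)
    c_free = free_rna_from_uv(uv, rna_idx, epsilon_rna=cfg.epsilon_rna,
                              path_length=cfg.uv_path_cm,
                              flow_calibration=cfg.flow_calibration)
    c_total, free_frac = c_lpx_total(p, s, c_free)

    btab = _read_table(out / "bragg_series.csv")
    area_full = np.full(len(t), np.nan)
    area_full[btab["frame"].to_numpy(int)] = btab["area"].to_numpy()
    area = ElutionTrace(t, area_full, "bragg_area")
    lpx_idx = btab["frame"].to_numpy(int)
    c_dif = normalize_bragg_area(area, lpx_idx, c_total)

    mtab = _read_table(out / "mals_series.csv")
    mfit = extrapolate_rg(mtab, degree=cfg.rg_extrapolation_degree)
    table = size_resolved_table(c_dif, mfit["rg_filled"].to_numpy(), s, p)
    _write_table(table, out / "size_table.csv", cfg, "quantify")
    binned = rebin_by_rg(table, s, p, n_bins=cfg.n_rg_bins)
    _write_table(binned, out / "size_table_binned.csv", cfg, "quantify")

    lines = [
        _header(cfg, "quantify").rstrip("\n"),
        f"free mRNA concentration   : {c_free:.4f} mg/mL",
        f"free mRNA fraction        : {100 * free_frac:.1f} %",
        f"expected free fraction    : {100 * s.expected_free_fraction:.1f} % (1 - charge ratio)",
        f"total LPX concentration   : {c_total:.4f} mg/mL  "
        f"(= (c_RNA_total - c_RNA_free) * MW_complex / MW_nucleotide)",
        f"complex MW                : {s.mw_nucleotide_plus_lipids:.0f} Da "
        f"(lipid per charge {s.mw_lipid_per_charge:.0f} Da)",
        f"LPX density               : {s.rho_lpx:.3f} g/mL",
        f"Bragg d-spacing (median)  : {np.nanmedian(btab['d_spacing']):.2f} nm",
        f"correlation length (med.) : {np.nanmedian(btab['corr_length']):.1f} nm",
    ]
    for weighting in ("mass", "number"):
        sm = distribution_summaries(table, weighting)
        lines.append(
            f"{weighting:>6}-weighted diameter  : D10 {sm['d10']:.0f} / D50 {sm['d50']:.0f} / "
            f"D90 {sm['d90']:.0f} nm, mode {sm['modal_diameter']:.0f} nm"
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n")
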