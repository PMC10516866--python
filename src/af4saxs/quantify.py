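"""Absolute size-resolved quantification of lipoplex formulations.

From (i) the formulation stoichiometry, (ii) the free-mRNA amount
measured by UV over the first elution peak, and (iii) the Bragg-area
elution trace, derive:

* the total LPX mass concentration
      c_LPXtotal = (c_RNAtotal - c_RNAfree) * MW_nucleotide+lipids / MW_nucleotide,
* the differential LPX concentration per frame, by normalizing the Bragg
  peak-area trace so it sums to c_LPXtotal (constant internal
  stoichiometry premise),
* per size fraction, with particles treated as solid spheres of density
  rho_LPX: R = sqrt(5/3) Rg, V = (4/3) pi R^3, m_p = V rho, particle
  number concentration n = c / m_p, mRNA copies per particle
  m_p N_A / (MW_nucleotide+lipids * n_nucleotide), and the differential
  mRNA copy concentration,
* D10/D50/D90 and mean/modal diameters under mass or number weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FormulationParams
from .processing import ElutionTrace
from .units import MG_TO_G, N_A, NM3_TO_ML

__all__ = [
    "DerivedStoichiometry",
    "derive_stoichiometry",
    "free_rna_from_uv",
    "c_lpx_total",
    "normalize_bragg_area",
    "size_resolved_table",
    "rebin_by_rg",
    "distribution_summaries",
]


@dataclass(frozen=True)
class DerivedStoichiometry:
    """Constants derived from the formulation composition."""

    mw_lipid_per_charge: float       # Da
    mw_nucleotide_plus_lipids: float  # Da
    rho_lpx: float                   # g/mL, mass-fraction volume additivity
    f_rna: float                     # RNA mass fraction of LPX material
    expected_free_fraction: float    # 1 - charge ratio


def derive_stoichiometry(p: FormulationParams) -> DerivedStoichiometry:
    """Lipid MW per charge, complex MW, and LPX density.

    One nucleotide charge binds one DOTMA plus its share of DOPE, so
    mw_lipid_per_charge = mw_DOTMA + mw_DOPE / (DOTMA:DOPE ratio).  The
    LPX density follows mass-fraction volume additivity:
    1/rho = f_RNA/rho_RNA + f_lipid/rho_lipid.
    """
    mw_lipid = p.mw_dotma + p.mw_dope / p.dotma_dope_molar_ratio
    mw_complex = p.mw_nucleotide + mw_lipid
    f_rna = p.mw_nucleotide / mw_complex
    rho = 1.0 / (f_rna / p.rho_rna + (1.0 - f_rna) / p.rho_lipid)
    return DerivedStoichiometry(
        mw_lipid_per_charge=float(mw_lipid),
        mw_nucleotide_plus_lipids=float(mw_complex),
        rho_lpx=float(rho),
        f_rna=float(f_rna),
        expected_free_fraction=float(1.0 - p.charge_ratio),
    )


def free_rna_from_uv(uv: ElutionTrace, rna_peak_frames,
                     epsilon_rna: float = 0.025, path_length: float = 1.0,
                     flow_calibration: float = 1.0) -> float:
    """Free-mRNA concentration [mg/mL] from the baseline-subtracted UV
    trace over the mRNA elution peak.

    Beer-Lambert: A = epsilon[mL ug^-1 cm^-1] * 1000 * c[mg/mL] * L[cm];
    the trapezoid trace integral divided by (epsilon * 1000 * L) and
    scaled by the flow/injection calibration factor gives the
    injected-equivalent concentration.
    """
    idx = np.asarray(rna_peak_frames, dtype=int)
    if idx.size == 0:
        raise ValueError("rna_peak_frames is empty")
    t = uv.frame_times[idx]
    v = uv.values[idx]
    area = np.trapezoid(v, t)
    if area < 0:
        raise ValueError("negative integrated UV area: check baseline subtraction")
    return float(flow_calibration * area / (epsilon_rna * 1.0e3 * path_length))


def c_lpx_total(p: FormulationParams, s: DerivedStoichiometry,
                c_rna_free: float) -> tuple[float, float]:
    """Total LPX concentration [mg/mL] and the free-RNA fraction.

    c_LPXtotal = (c_RNAtotal - c_RNAfree) * MW_complex / MW_nucleotide.
    """
    if c_rna_free > p.c_rna_total:
        raise ValueError("free RNA exceeds total RNA concentration")
    c_total = (p.c_rna_total - c_rna_free) * (
        s.mw_nucleotide_plus_lipids / p.mw_nucleotide
    )
    return float(c_total), float(c_rna_free / p.c_rna_total)


def normalize_bragg_area(area: ElutionTrace, lpx_frames,
                         c_total: float) -> ElutionTrace:
    """Differential LPX concentration trace from the Bragg-area trace.

    The area trace over the LPX peak is scaled so the per-frame values sum
    to ``c_total`` exactly (NaN outside ``lpx_frames``).
    """
    idx = np.asarray(lpx_frames, dtype=int)
    if c_total <= 0:
        raise ValueError("c_total must be positive")
    a = area.values[idx]
    if np.any(a < -1e-12 * np.nanmax(np.abs(a))):
        raise ValueError("negative Bragg areas over the LPX peak")
    tot = np.nansum(a)
    if tot <= 0:
        raise ValueError("zero total Bragg area")
    vals = np.full(len(area), np.nan)
    vals[idx] = np.where(np.isnan(a), np.nan, np.maximum(a, 0.0)) * (c_total / tot)
    # renormalize if NaN frames dropped mass
    good = np.nansum(vals)
    if good > 0:
        vals = vals * (c_total / good)
    return ElutionTrace(area.frame_times, vals, "bragg_area")


def size_resolved_table(c_dif: ElutionTrace, rg_per_frame,
                        s: DerivedStoichiometry,
                        p: FormulationParams) -> pd.DataFrame:
    """Per-frame size-fraction table.

    Columns: time_min, rg [nm], c_lpx_dif [mg/mL], radius [nm],
    volume [nm^3], m_p [g], n_lpx_dif [particles/mL],
    n_rna_per_particle [copies], n_rna_dif [copies/mL].
    Frames with c_lpx_dif = NaN or 0 are dropped; a frame carrying mass
    but no Rg raises.
    """
    rg = np.asarray(rg_per_frame, dtype=float)
    if len(rg) != len(c_dif):
        raise ValueError("rg_per_frame must align with the concentration trace")
    c = c_dif.values
    keep = np.isfinite(c) & (c > 0)
    if np.any(keep & ~np.isfinite(rg)):
        raise ValueError(
            "missing Rg on a frame with LPX mass; enable Rg extrapolation"
        )
    t = c_dif.frame_times[keep]
    c = c[keep]
    rg = rg[keep]
    radius = np.sqrt(5.0 / 3.0) * rg
    volume = (4.0 / 3.0) * np.pi * radius**3
    m_p = volume * NM3_TO_ML * s.rho_lpx
    n_lpx = c * MG_TO_G / m_p
    denom = s.mw_nucleotide_plus_lipids * p.n_nucleotide
    n_rna_per = m_p * N_A / denom
    n_rna_dif = c * MG_TO_G * N_A / denom
    return pd.DataFrame(
        dict(
            time_min=t, rg=rg, c_lpx_dif=c, radius=radius, volume=volume,
            m_p=m_p, n_lpx_dif=n_lpx, n_rna_per_particle=n_rna_per,
            n_rna_dif=n_rna_dif,
        )
    )


def rebin_by_rg(table: pd.DataFrame, s: DerivedStoichiometry,
                p: FormulationParams, n_bins: int = 10) -> pd.DataFrame:
    """Aggregate the per-frame table into equal-Rg bins (bar-chart style).

    Mass is summed per bin; the representative Rg is the mass-weighted
    mean, and the derived per-particle quantities are recomputed from it.
    """
    edges = np.linspace(table["rg"].min(), table["rg"].max() * (1 + 1e-12),
                        n_bins + 1)
    which = np.digitize(table["rg"], edges) - 1
    rows = []
    for b in range(n_bins):
        sub = table[which == b]
        if len(sub) == 0 or sub["c_lpx_dif"].sum() <= 0:
            continue
        c = sub["c_lpx_dif"].sum()
        rg = np.average(sub["rg"], weights=sub["c_lpx_dif"])
        rows.append((0.5 * (edges[b] + edges[b + 1]), rg, c))
    binned = pd.DataFrame(rows, columns=["rg_bin_center", "rg", "c_lpx_dif"])
    trace = ElutionTrace(np.arange(len(binned), dtype=float),
                         binned["c_lpx_dif"].to_numpy(), "bragg_area")
    out = size_resolved_table(trace, binned["rg"].to_numpy(), s, p)
    out = out.drop(columns="time_min")
    out.insert(0, "rg_bin_center", binned["rg_bin_center"].to_numpy())
    return out


def distribution_summaries(table: pd.DataFrame, weighting: str = "mass") -> dict:
    """D10/D50/D90, weighted mean diameter and modal diameter [nm].

    ``weighting='mass'`` uses c_lpx_dif, ``'number'`` uses n_lpx_dif.
    The cumulative distribution over diameter 2R interpolates linearly
    between bin midpoints.
    """
    if weighting not in ("mass", "number"):
        raise ValueError("weighting must be 'mass' or 'number'")
    w = table["c_lpx_dif" if weighting == "mass" else "n_lpx_dif"].to_numpy(float)
    d = 2.0 * table["radius"].to_numpy(float)
    if len(d) == 0 or np.all(w <= 0):
        raise ValueError("table has no positive weights")
    order = np.argsort(d)
    d, w = d[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum = cum / np.sum(w)
    def percentile(f):
        return float(np.interp(f, cum, d))
    return dict(
        weighting=weighting,
        d10=percentile(0.10),
        d50=percentile(0.50),
        d90=percentile(0.90),
        mean_diameter=float(np.average(d, weights=w)),
        modal_diameter=float(d[np.argmax(w)]),
    )
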