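"""Per-frame Berry analysis of multi-angle light-scattering records.

The first-order Berry transform plots sqrt(Kc / R(theta)) against
q_LS^2 with q_LS = (4 pi n0 / lambda0) sin(theta / 2).  A straight-line
fit gives MW = 1 / b^2 from the intercept b and Rg = sqrt(6 m / b) from
the slope m.  Molecular weights follow the unit convention of Kc: with
Kc expressed per kDa (as the synthetic generator does), MW comes out in
kDa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Fractogram
from .processing import ElutionTrace

__all__ = [
    "MalsFrameResult",
    "MalsSettings",
    "q_light",
    "berry_records",
    "berry_fit",
    "mals_series",
    "extrapolate_rg",
    "DEFAULT_ANGLES",
]

#: default detection angles [deg]: 9 angles spanning 35..145 degrees
DEFAULT_ANGLES = np.linspace(35.0, 145.0, 9)


@dataclass(frozen=True)
class MalsSettings:
    lambda0: float = 658.0     # laser wavelength in vacuo [nm]
    n0: float = 1.33           # solvent refractive index
    min_angles: int = 9        # minimum active angles for a reported value


@dataclass(frozen=True)
class MalsFrameResult:
    rg: float                 # nm (0 with low_signal flag when slope <= 0)
    mw: float                 # kDa (Kc unit convention)
    n_angles_used: int
    r_squared: float
    low_signal: bool = False
    angle_truncated: bool = False


def q_light(angles_deg: np.ndarray, lambda0: float = 658.0,
            n0: float = 1.33) -> np.ndarray:
    """Light-scattering momentum transfer [nm^-1] for angles in degrees."""
    theta = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return (4.0 * np.pi * n0 / lambda0) * np.sin(theta / 2.0)


def berry_records(mw: float, rg: float, kc: float,
                  angles_deg: np.ndarray = DEFAULT_ANGLES,
                  lambda0: float = 658.0, n0: float = 1.33) -> np.ndarray:
    """Noiseless (angle, excess Rayleigh ratio) records from the inverse
    first-order Berry relation — the forward model the simulator uses.

    sqrt(Kc / R) = b + m q^2 with b = 1/sqrt(MW), m = b Rg^2 / 6.
    """
    if mw <= 0 or rg < 0 or kc <= 0:
        raise ValueError("mw, kc must be positive and rg non-negative")
    q = q_light(angles_deg, lambda0, n0)
    b = 1.0 / np.sqrt(mw)
    m = b * rg**2 / 6.0
    r = kc / (b + m * q**2) ** 2
    return np.column_stack([np.asarray(angles_deg, dtype=float), r])


def berry_fit(records: np.ndarray, kc: float,
              settings: MalsSettings = MalsSettings()) -> MalsFrameResult:
    """First-order Berry fit of one frame's MALS records.

    Forward (small-angle) records are dropped greedily while doing so
    improves the straight-line r^2 and at least ``min_angles`` remain —
    mirroring the practice of limiting forward angles when large particles
    dominate the low-q signal.  A non-positive slope yields rg = 0 with
    the ``low_signal`` flag.
    """
    records = np.atleast_2d(np.asarray(records, dtype=float))
    if kc <= 0:
        raise ValueError("kc must be positive")
    usable = records[records[:, 1] > 0]
    if len(usable) < settings.min_angles:
        raise ValueError(
            f"only {len(usable)} usable angles; need {settings.min_angles}"
        )
    usable = usable[np.argsort(usable[:, 0])]
    q2 = q_light(usable[:, 0], settings.lambda0, settings.n0) ** 2
    y = np.sqrt(kc / usable[:, 1])

    def linfit(x, yy):
        b_slope, b_icpt = np.polyfit(x, yy, 1)
        pred = b_icpt + b_slope * x
        ss_res = np.sum((yy - pred) ** 2)
        ss_tot = np.sum((yy - yy.mean()) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return b_icpt, b_slope, r2

    start = 0
    b, m, r2 = linfit(q2, y)
    while len(q2) - (start + 1) >= settings.min_angles:
        b2, m2, r2_try = linfit(q2[start + 1:], y[start + 1:])
        if r2_try > r2 + 1e-12:
            start += 1
            b, m, r2 = b2, m2, r2_try
        else:
            break
    n_used = len(q2) - start
    truncated = start > 0
    if b <= 0:
        return MalsFrameResult(rg=0.0, mw=np.inf, n_angles_used=n_used,
                               r_squared=r2, low_signal=True,
                               angle_truncated=truncated)
    mw = 1.0 / b**2
    if m <= 0:
        return MalsFrameResult(rg=0.0, mw=float(mw), n_angles_used=n_used,
                               r_squared=r2, low_signal=True,
                               angle_truncated=truncated)
    rg = float(np.sqrt(6.0 * m / b))
    return MalsFrameResult(rg=rg, mw=float(mw), n_angles_used=n_used,
                           r_squared=float(r2), low_signal=False,
                           angle_truncated=truncated)


def mals_series(fr: Fractogram, kc_per_frame: ElutionTrace | np.ndarray,
                settings: MalsSettings = MalsSettings()) -> pd.DataFrame:
    """Per-frame Berry results as a table (NaN/flags where unusable).

    Frames whose median Rayleigh ratio is below 3x the baseline MAD of the
    run are marked ``low_signal`` and skipped; the baseline is estimated
    from the lowest-signal fifth of the frames.
    """
    if not fr.mals:
        raise ValueError("fractogram carries no MALS records")
    kc = kc_per_frame.values if isinstance(kc_per_frame, ElutionTrace) else np.asarray(kc_per_frame, dtype=float)
    if len(kc) != fr.n_frames:
        raise ValueError("kc_per_frame must match the number of frames")
    med = np.array([
        np.median(np.atleast_2d(m)[:, 1]) if np.asarray(m).size else 0.0
        for m in fr.mals
    ])
    k = max(1, fr.n_frames // 5)
    base = np.sort(med)[:k]
    mad = np.median(np.abs(base - np.median(base)))
    thresh = 3.0 * mad if mad > 0 else 0.0
    rows = []
    for i in range(fr.n_frames):
        t = fr.frame_times[i]
        rec = np.atleast_2d(fr.mals[i])
        if rec.size == 0 or med[i] < thresh or kc[i] <= 0:
            rows.append((t, np.nan, np.nan, 0, np.nan, True, False))
            continue
        try:
            res = berry_fit(rec, kc[i], settings)
        except ValueError:
            rows.append((t, np.nan, np.nan, 0, np.nan, True, False))
            continue
        rows.append((t, res.rg if not res.low_signal else np.nan,
                     res.mw, res.n_angles_used, res.r_squared,
                     res.low_signal, res.angle_truncated))
    return pd.DataFrame(
        rows,
        columns=["time_min", "rg", "mw", "n_angles_used", "r_squared",
                 "low_signal", "angle_truncated"],
    )


def extrapolate_rg(series: pd.DataFrame, degree: int = 2) -> pd.DataFrame:
    """Fill flagged/missing Rg values by a polynomial fit of Rg vs time.

    Returns a copy with an ``rg_filled`` column and a boolean
    ``rg_extrapolated`` marker; used for large-particle frames whose Berry
    fit is unreliable.
    """
    out = series.copy()
    good = out["rg"].notna() & ~out["low_signal"]
    if good.sum() < degree + 1:
        raise ValueError("too few reliable Rg values to extrapolate from")
    coef = np.polyfit(out.loc[good, "time_min"], out.loc[good, "rg"], degree)
    filled = out["rg"].to_numpy(dtype=float)
    missing = ~good.to_numpy()
    filled[missing] = np.polyval(coef, out.loc[missing, "time_min"])
    out["rg_filled"] = np.maximum(filled, 0.0)
    out["rg_extrapolated"] = missing
    return out
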