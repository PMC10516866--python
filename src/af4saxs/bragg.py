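"""Lorentzian Bragg-peak analysis of lipoplex scattering curves.

Each lipoplex curve carries a single Bragg peak from the lamellar repeat
inside the particles.  The peak is fitted with a Lorentzian

    I(q) = I0 + (2 A / pi) * w / (4 (q - qc)^2 + w^2)

(optionally on top of a power-law baseline c * q^-x, x in [3, 4]), giving
the repeat distance d = 2 pi / qc, the positional correlation length
xi = 2 / w (w is the FWHM), and the peak area A — the measure of the
amount of ordered material used for quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import Fractogram, ScatteringCurve
from .processing import ElutionTrace

__all__ = [
    "BraggPeakFit",
    "BraggFitError",
    "lorentzian",
    "fit_lorentzian",
    "bragg_series",
    "area_over_width",
    "DEFAULT_BRAGG_WINDOW",
]

DEFAULT_BRAGG_WINDOW = (0.7, 1.4)   # nm^-1, brackets the ~1 nm^-1 peak


class BraggFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class BraggPeakFit:
    i0_base: float          # baseline level at the peak [curve units]
    area: float             # A [curve units * nm^-1]
    width: float            # w, FWHM [nm^-1]
    center: float           # qc [nm^-1]
    d_spacing: float        # 2 pi / qc [nm]
    corr_length: float      # 2 / w [nm]
    fit_window: tuple[float, float]
    residual_rms: float
    baseline: str = "constant"
    power_law: tuple[float, float] | None = None  # (c, x) when baseline='power_law'

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")
        lo, hi = self.fit_window
        if not lo <= self.center <= hi:
            raise ValueError("center outside fit window")


def lorentzian(q, i0, a, w, qc):
    """Lorentzian peak on a constant baseline; ``a`` is the peak area and
    ``w`` the FWHM."""
    return i0 + (2.0 * a / np.pi) * w / (4.0 * (q - qc) ** 2 + w**2)


def _lorentzian_pl(q, i0, a, w, qc, c_pl, x):
    return lorentzian(q, i0, a, w, qc) + c_pl * q**-x


def fit_lorentzian(c: ScatteringCurve, window: tuple[float, float] = DEFAULT_BRAGG_WINDOW,
                   baseline: str = "constant") -> BraggPeakFit:
    """Weighted nonlinear least-squares Lorentzian fit inside ``window``.

    Initial guesses: qc at the window maximum, w from the half-maximum
    crossing distance, A from the trapezoid area above baseline.  Bounds:
    qc inside the window, 0 < w < window span, A >= 0.
    """
    if baseline not in ("constant", "power_law"):
        raise ValueError("baseline must be 'constant' or 'power_law'")
    lo, hi = window
    m = (c.q >= lo) & (c.q <= hi)
    if m.sum() < 10:
        raise BraggFitError("fit window must contain at least 10 points")
    q, i, s = c.q[m], c.intensity[m], c.sigma[m]

    # locate the peak on the detrended window: lipoplex curves sit on a
    # steep power-law decay, so the raw argmax can be the window edge even
    # when a clear interior peak exists
    edge = max(3, len(q) // 10)
    if np.all(i > 0):
        # straight line in log-log through the window edges
        x0, x1 = np.log(q[:edge]).mean(), np.log(q[-edge:]).mean()
        y0, y1 = np.log(i[:edge]).mean(), np.log(i[-edge:]).mean()
        trend = np.exp(y0 + (np.log(q) - x0) * (y1 - y0) / (x1 - x0))
    else:
        x0, x1 = q[:edge].mean(), q[-edge:].mean()
        y0, y1 = i[:edge].mean(), i[-edge:].mean()
        trend = y0 + (q - x0) * (y1 - y0) / (x1 - x0)
    resid = i - trend
    k = int(np.argmax(resid))
    med_sig = float(np.median(s[s > 0])) if np.any(s > 0) else 0.0
    floor = max(3.0 * med_sig, 1e-6 * float(np.max(np.abs(i))))
    if k == 0 or k == len(i) - 1 or resid[k] <= floor:
        raise BraggFitError("no interior local maximum inside the fit window")
    qc0 = q[k]
    height0 = float(resid[k])
    half = 0.5 * height0
    above = resid >= half
    left = q[np.flatnonzero(above)[0]]
    right = q[np.flatnonzero(above)[-1]]
    w0 = max(float(right - left), float(q[1] - q[0]))
    a0 = max(float(np.trapezoid(np.maximum(resid, 0.0), q)), 1e-12)
    base0 = float(min(i[0], i[-1]))
    span = hi - lo
    sig = np.where(s > 0, s, np.max(s) if np.any(s > 0) else 1.0)

    if baseline == "constant":
        p0 = [base0, a0, w0, qc0]
        bounds = ([-np.inf, 0.0, 1e-6 * span, lo], [np.inf, np.inf, span, hi])
        model = lorentzian
    else:
        # seed the power-law with the window-edge levels, x = 3.6
        x0 = 3.6
        c0 = base0 * q[0] ** x0 if base0 > 0 else 1e-12
        p0 = [0.0, a0, w0, qc0, c0, x0]
        bounds = (
            [-np.inf, 0.0, 1e-6 * span, lo, 0.0, 3.0],
            [np.inf, np.inf, span, hi, np.inf, 4.0],
        )
        model = _lorentzian_pl

    try:
        popt, _ = curve_fit(
            model, q, i, p0=p0, sigma=sig, absolute_sigma=True,
            bounds=bounds, maxfev=20000,
        )
    except RuntimeError as exc:
        raise BraggFitError(f"Lorentzian fit did not converge: {exc}") from exc

    resid = i - model(q, *popt)
    rms = float(np.sqrt(np.mean((resid / sig) ** 2)))
    i0_base, a, w, qc = (float(v) for v in popt[:4])
    power_law = None
    if baseline == "power_law":
        power_law = (float(popt[4]), float(popt[5]))
        i0_base = float(popt[0] + popt[4] * qc ** -popt[5])
    return BraggPeakFit(
        i0_base=i0_base,
        area=a,
        width=w,
        center=qc,
        d_spacing=float(2.0 * np.pi / qc),
        corr_length=float(2.0 / w),
        fit_window=(lo, hi),
        residual_rms=rms,
        baseline=baseline,
        power_law=power_law,
    )


_SERIES_COLS = ["time_min", "qc", "w", "area", "d_spacing", "corr_length",
                "i0_base", "residual_rms"]


def bragg_series(fr: Fractogram, peak_frames,
                 window: tuple[float, float] = DEFAULT_BRAGG_WINDOW,
                 baseline: str = "constant") -> tuple[pd.DataFrame, ElutionTrace]:
    """Per-frame Lorentzian fits over ``peak_frames``.

    Frames whose fit fails carry NaN rows (the elution axis is preserved
    for quantification); if every frame fails, raises.  Returns the fit
    table and the Bragg-area elution trace (NaN outside ``peak_frames``).
    """
    peak_frames = np.asarray(peak_frames, dtype=int)
    if peak_frames.size == 0:
        raise ValueError("peak_frames is empty")
    rows = []
    n_ok = 0
    for idx in peak_frames:
        t = fr.frame_times[idx]
        try:
            f = fit_lorentzian(fr.saxs_frames[idx], window=window, baseline=baseline)
            rows.append((t, f.center, f.width, f.area, f.d_spacing,
                         f.corr_length, f.i0_base, f.residual_rms))
            n_ok += 1
        except (BraggFitError, ValueError):
            rows.append((t,) + (np.nan,) * 7)
    if n_ok == 0:
        raise BraggFitError("Bragg fit failed on every requested frame")
    table = pd.DataFrame(rows, columns=_SERIES_COLS, index=pd.Index(peak_frames, name="frame"))
    area_full = np.full(fr.n_frames, np.nan)
    area_full[peak_frames] = table["area"].to_numpy()
    trace = ElutionTrace(fr.frame_times, area_full, "bragg_area")
    return table, trace


def area_over_width(series: pd.DataFrame) -> ElutionTrace:
    """Per-frame peak area divided by peak width (missing where either is)."""
    if len(series) == 0:
        raise ValueError("empty Bragg series")
    vals = (series["area"] / series["w"]).to_numpy(dtype=float)
    return ElutionTrace(series["time_min"].to_numpy(dtype=float), vals, "bragg_area")
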