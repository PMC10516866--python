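"""Fractogram-level processing: buffer selection/subtraction, frame
averaging, and scalar elution traces."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import Fractogram, ScatteringCurve

__all__ = [
    "ElutionTrace",
    "select_buffer_frames",
    "subtract_buffer",
    "elution_trace",
    "average_frames",
    "peak_frames",
]

TRACE_KINDS = ("saxs_integrated", "saxs_low_q", "uv", "ls90", "bragg_area")


@dataclass(frozen=True)
class ElutionTrace:
    """Scalar detector/derived signal per elution frame."""

    frame_times: np.ndarray   # min
    values: np.ndarray
    kind: str

    def __post_init__(self):
        t = np.asarray(self.frame_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "frame_times", t)
        object.__setattr__(self, "values", v)
        if len(t) != len(v):
            raise ValueError("values must match frame_times length")
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"kind must be one of {TRACE_KINDS}")

    def __len__(self) -> int:
        return len(self.values)


def select_buffer_frames(fr: Fractogram, window="auto",
                         min_run: int = 10) -> np.ndarray:
    """Indices of frames to use as buffer (blank) reference.

    ``window`` may be an explicit ``(start, stop)`` half-open index range,
    or ``"auto"``: the longest contiguous run (>= ``min_run`` frames) whose
    integrated intensity lies within 2 median-absolute-deviations of the
    pre-elution baseline median.
    """
    n = fr.n_frames
    if window != "auto":
        start, stop = window
        if not (0 <= start < stop <= n):
            raise ValueError("explicit buffer window out of range")
        return np.arange(start, stop)
    totals = np.array([np.trapezoid(f.intensity, f.q) for f in fr.saxs_frames])
    # pre-elution baseline: the first fifth of the run; the MAD is scaled
    # to a robust sigma (x1.4826) so "within 2 deviations" keeps ~95% of
    # genuine baseline frames
    k = max(min_run, n // 5)
    base = totals[:k]
    med = np.median(base)
    sig = 1.4826 * np.median(np.abs(base - med))
    span = totals.max() - med
    if sig > 0.1 * span and span > 0:
        raise ValueError(
            "pre-elution region is not flat (no baseline); "
            "pass an explicit buffer window"
        )
    tol = 2.0 * sig if sig > 0 else 2.0 * np.abs(med) * 1e-6 + 1e-30
    # judge frames on a 5-frame rolling median so single-frame noise does
    # not fragment a genuine baseline run
    padded = np.concatenate([totals[2:0:-1], totals, totals[-2:-4:-1]])
    smooth = np.array([np.median(padded[j:j + 5]) for j in range(n)])
    ok = np.abs(smooth - med) <= tol
    best_start, best_len = -1, 0
    run_start = None
    for idx in range(n + 1):
        inside = idx < n and ok[idx]
        if inside and run_start is None:
            run_start = idx
        elif not inside and run_start is not None:
            length = idx - run_start
            if length > best_len:
                best_start, best_len = run_start, length
            run_start = None
    if best_len < min_run:
        raise ValueError(
            "no contiguous baseline run found; pass an explicit buffer window"
        )
    return np.arange(best_start, best_start + best_len)


def subtract_buffer(fr: Fractogram, buffer_idx) -> Fractogram:
    """Subtract the mean of the buffer frames from every frame.

    Sigma is propagated in quadrature: sigma'^2 = sigma^2 + sigma_buf^2 / n.
    """
    buffer_idx = np.asarray(buffer_idx, dtype=int)
    if buffer_idx.size == 0:
        raise ValueError("buffer index set is empty")
    I = fr.intensity_matrix()
    S = fr.sigma_matrix()
    buf = I[buffer_idx].mean(axis=0)
    var_buf = (S[buffer_idx] ** 2).sum(axis=0) / buffer_idx.size**2
    new_frames = []
    for f in fr.saxs_frames:
        new_frames.append(
            replace(
                f,
                intensity=f.intensity - buf,
                sigma=np.sqrt(f.sigma**2 + var_buf),
            )
        )
    return replace(fr, saxs_frames=tuple(new_frames))


def elution_trace(fr: Fractogram, kind: str,
                  q_window: tuple[float, float] | None = None) -> ElutionTrace:
    """Scalar trace per frame.

    * ``saxs_integrated``: trapezoid of I over ``q_window``
    * ``saxs_low_q``: mean I over the lowest 5 grid points of ``q_window``
    * ``uv``: the UV 260 nm detector trace
    * ``ls90``: excess Rayleigh ratio at the angle closest to 90 degrees
    """
    if kind in ("saxs_integrated", "saxs_low_q"):
        q = fr.q
        if q_window is None:
            q_window = (q[0], q[-1])
        m = (q >= q_window[0]) & (q <= q_window[1])
        if not m.any():
            raise ValueError("empty q-window")
        if kind == "saxs_integrated":
            vals = np.array(
                [np.trapezoid(f.intensity[m], q[m]) for f in fr.saxs_frames]
            )
        else:
            sel = np.flatnonzero(m)[:5]
            vals = np.array([f.intensity[sel].mean() for f in fr.saxs_frames])
    elif kind == "uv":
        vals = fr.uv_260.copy()
    elif kind == "ls90":
        if not fr.mals:
            raise ValueError("fractogram carries no MALS records")
        vals = np.empty(fr.n_frames)
        for i, rec in enumerate(fr.mals):
            rec = np.atleast_2d(rec)
            if rec.size == 0:
                vals[i] = np.nan
                continue
            j = np.argmin(np.abs(rec[:, 0] - 90.0))
            vals[i] = rec[j, 1]
    else:
        raise ValueError(f"unknown trace kind {kind!r}")
    return ElutionTrace(fr.frame_times, vals, kind)


def average_frames(fr: Fractogram, idx) -> ScatteringCurve:
    """Inverse-variance-weighted pointwise mean of the selected frames.

    Falls back to an unweighted mean (label-flagged) when any sigma is
    zero, where inverse-variance weights are undefined.
    """
    idx = np.asarray(idx, dtype=int)
    if idx.size == 0:
        raise ValueError("index set is empty")
    I = fr.intensity_matrix()[idx]
    S = fr.sigma_matrix()[idx]
    if np.any(S <= 0):
        mean = I.mean(axis=0)
        sig = np.sqrt((S**2).sum(axis=0)) / idx.size
        label = f"unweighted mean of {idx.size} frames (zero sigmas)"
    else:
        w = 1.0 / S**2
        wsum = w.sum(axis=0)
        mean = (w * I).sum(axis=0) / wsum
        sig = 1.0 / np.sqrt(wsum)
        label = f"weighted mean of {idx.size} frames"
    return ScatteringCurve(fr.q, mean, sig, label=label)


def peak_frames(trace: ElutionTrace, threshold: float = 0.10,
                time_window: tuple[float, float] | None = None) -> np.ndarray:
    """Frames where the trace exceeds ``threshold`` x its maximum,
    optionally restricted to an elution-time window."""
    v = trace.values
    m = np.isfinite(v)
    if time_window is not None:
        m &= (trace.frame_times >= time_window[0]) & (trace.frame_times <= time_window[1])
    if not m.any():
        raise ValueError("no frames in window")
    vmax = np.nanmax(v[m])
    return np.flatnonzero(m & (v >= threshold * vmax))
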