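"""Model-free analysis of single scattering curves.

Guinier fit (Rg, I(0)), Kratky representation, power-law (Porod) exponent,
molecular-weight estimation from the volume of correlation, and a
regularized indirect Fourier transform for the pair-distance distribution
p(r) with Dmax selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .io import ScatteringCurve
from .units import DA_TO_KDA, NM_TO_ANGSTROM

__all__ = [
    "GuinierResult",
    "MWEstimate",
    "PofRResult",
    "guinier",
    "porod_exponent",
    "kratky",
    "mw_from_vc",
    "pofr",
    "VC_PROTEIN_DIVISOR",
    "VC_RNA_DIVISOR",
    "VC_RNA_EXPONENT",
]

# Volume-of-correlation MW calibration (Angstrom/Da convention):
# protein: MW = QR / 0.1231; RNA: MW = (QR / 0.00934)^0.808.
# These are the published empirical constants; override per call if a
# different calibration is preferred.
VC_PROTEIN_DIVISOR = 0.1231
VC_RNA_DIVISOR = 0.00934
VC_RNA_EXPONENT = 0.808


@dataclass(frozen=True)
class GuinierResult:
    """Low-q Guinier approximation ln I = ln I(0) - q^2 Rg^2 / 3."""

    rg: float                     # nm
    i0: float                     # curve units
    fit_range: tuple[float, float]
    q_rg_max: float
    r_squared: float
    n_points: int

    def __post_init__(self):
        if self.rg <= 0:
            raise ValueError("rg must be positive")


@dataclass(frozen=True)
class MWEstimate:
    mw: float                     # kDa
    vc: float                     # nm^2
    qr: float                     # nm^3
    molecule_class: str           # 'protein' | 'rna'
    method: str = "volume_of_correlation"
    truncated: bool = False       # curve did not reach q = 3 nm^-1


@dataclass(frozen=True)
class PofRResult:
    r: np.ndarray                 # nm
    p: np.ndarray                 # arbitrary, p(0)=p(dmax)=0
    dmax: float                   # nm
    rg_real: float                # nm, from second moment of p(r)
    residual: float               # weighted RMS misfit of the regularized fit


class NoGuinierRegionError(ValueError):
    """The low-q data have no negative ln I vs q^2 slope."""


def _weighted_linfit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least-squares line y = a + b x; returns (a, b, r_squared)."""
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    sxy = np.sum(w * (x - xm) * (y - ym))
    b = sxy / sxx
    a = ym - b * xm
    ss_res = np.sum(w * (y - a - b * x) ** 2)
    ss_tot = np.sum(w * (y - ym) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return a, b, r2


def guinier(c: ScatteringCurve, q_rg_limit: float = 1.3,
            min_points: int = 5) -> GuinierResult:
    """Self-consistent Guinier fit over the largest low-q window with
    q * Rg <= ``q_rg_limit``.

    Starts from the lowest usable q with ``min_points`` points, then grows
    the window and refits until the q*Rg limit binds.
    """
    pos = c.intensity > 0
    # leading run of usable low-q points
    usable = np.flatnonzero(~pos)
    stop = usable[0] if usable.size else len(c)
    q = c.q[:stop]
    i = c.intensity[:stop]
    s = c.sigma[:stop]
    if len(q) < min_points:
        raise ValueError("fewer than 5 usable low-q points with I > 0")
    # weights on ln I: sigma_lnI = sigma / I (fall back to equal weights)
    sig_ln = np.where(s > 0, s / i, np.nan)
    sig_ln = np.where(np.isfinite(sig_ln), sig_ln, np.nanmax(sig_ln) if np.any(np.isfinite(sig_ln)) else 1.0)
    if not np.any(sig_ln > 0):
        sig_ln = np.ones_like(q)
    w_all = 1.0 / sig_ln**2
    x_all = q**2
    y_all = np.log(i)

    n = min_points
    for _ in range(100):
        a, b, r2 = _weighted_linfit(x_all[:n], y_all[:n], w_all[:n])
        if b >= 0:
            raise NoGuinierRegionError("no Guinier region: non-negative slope")
        rg = float(np.sqrt(-3.0 * b))
        n_new = int(np.searchsorted(q, q_rg_limit / rg, side="right"))
        n_new = max(min_points, min(n_new, len(q)))
        if n_new == n:
            break
        n = n_new
    return GuinierResult(
        rg=rg,
        i0=float(np.exp(a)),
        fit_range=(float(q[0]), float(q[n - 1])),
        q_rg_max=float(q[n - 1] * rg),
        r_squared=float(r2),
        n_points=n,
    )


def porod_exponent(c: ScatteringCurve, q_window: tuple[float, float]):
    """Power-law fit I = i0_pl * q^-x over ``q_window`` (log-log weighted
    linear fit).

    Returns ``(x, i0_pl, peak_flag)``; ``peak_flag`` is True when an
    interior local maximum (e.g. a Bragg peak) is detected inside the
    window, in which case the exponent is biased and the window should be
    moved.
    """
    lo, hi = q_window
    m = (c.q >= lo) & (c.q <= hi)
    if m.sum() < 6:
        raise ValueError("Porod window must contain at least 6 points")
    q, i, s = c.q[m], c.intensity[m], c.sigma[m]
    if np.any(i <= 0):
        raise ValueError("non-positive intensities in Porod window")
    sig_ln = np.where(s > 0, s / i, np.inf)
    if not np.any(np.isfinite(sig_ln)):
        sig_ln = np.ones_like(q)
    else:
        sig_ln = np.where(np.isfinite(sig_ln), sig_ln, np.max(sig_ln[np.isfinite(sig_ln)]))
    w = 1.0 / sig_ln**2
    a, b, _ = _weighted_linfit(np.log(q), np.log(i), w)
    # interior local maximum above 3-sigma of its neighbours suggests a peak
    peak_flag = False
    if len(i) >= 5:
        interior = np.arange(2, len(i) - 2)
        for k in interior:
            if i[k] > i[k - 2] and i[k] > i[k + 2]:
                rise = i[k] - 0.5 * (i[k - 2] + i[k + 2])
                noise = s[k] if s[k] > 0 else 0.0
                if rise > max(3.0 * noise, 0.02 * i[k]):
                    peak_flag = True
                    break
    return float(-b), float(np.exp(a)), peak_flag


def kratky(c: ScatteringCurve) -> tuple[np.ndarray, np.ndarray]:
    """Kratky representation (q, q^2 I(q)); a pointwise transform."""
    return c.q, c.q**2 * c.intensity


def mw_from_vc(c: ScatteringCurve, g: GuinierResult, molecule_class: str,
               q_max: float = 3.0,
               protein_divisor: float = VC_PROTEIN_DIVISOR,
               rna_divisor: float = VC_RNA_DIVISOR,
               rna_exponent: float = VC_RNA_EXPONENT) -> MWEstimate:
    """Molecular weight from the volume of correlation.

    Vc = I(0) / integral(q I dq) taken from q = 0 (Guinier model below
    the first measured point) to ``q_max`` (default 3 nm^-1 = 0.3 A^-1,
    the cutoff of the published calibration protocol).  QR = Vc^2 / Rg;
    the empirical power-law calibration (Angstrom units) maps QR to MW in
    Da.  Concentration and intensity scale cancel through I(0).
    """
    if molecule_class not in ("protein", "rna"):
        raise ValueError("molecule_class must be 'protein' or 'rna'")
    sel = c.q <= q_max
    q, i = c.q[sel], c.intensity[sel]
    truncated = c.q[-1] < q_max * (1.0 - 1e-9)
    # analytic Guinier piece on [0, q_min]
    rg2 = g.rg**2
    head = g.i0 * 3.0 / (2.0 * rg2) * (1.0 - np.exp(-q[0] ** 2 * rg2 / 3.0))
    body = np.trapezoid(q * i, q)
    total = head + body
    if total <= 0:
        raise ValueError("non-positive q*I integral")
    vc_nm2 = g.i0 / total
    vc_A2 = vc_nm2 * NM_TO_ANGSTROM**2
    rg_A = g.rg * NM_TO_ANGSTROM
    qr_A3 = vc_A2**2 / rg_A
    if molecule_class == "protein":
        mw_da = qr_A3 / protein_divisor
    else:
        mw_da = (qr_A3 / rna_divisor) ** rna_exponent
    return MWEstimate(
        mw=float(mw_da * DA_TO_KDA),
        vc=float(vc_nm2),
        qr=float(qr_A3 / NM_TO_ANGSTROM**3),
        molecule_class=molecule_class,
        truncated=bool(truncated),
    )


def _ift_design(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Design matrix of I(q) = 4 pi * integral p(r) sinc(q r) dr on the
    trapezoid rule over the r grid (interior nodes only; endpoints are
    pinned to zero)."""
    dr = r[1] - r[0]
    qr = np.outer(q, r[1:-1])
    K = 4.0 * np.pi * np.sinc(qr / np.pi) * dr
    return K


def pofr(c: ScatteringCurve, dmax_guess: float, n_r: int = 50,
         candidate_span: tuple[float, float] = (0.6, 1.6),
         n_candidates: int = 21) -> PofRResult:
    """Pair-distance distribution by regularized indirect Fourier transform.

    p(r) is represented on an ``n_r``-point grid over [0, dmax] with
    p(0) = p(dmax) = 0 enforced exactly and non-negativity imposed.  A
    second-difference (smoothness) penalty is weighted by the largest
    multiplier whose misfit stays within 5% of the unregularized optimum.
    Dmax is the smallest candidate around ``dmax_guess`` whose residual is
    within 5% of the best candidate's.
    """
    if dmax_guess <= 0:
        raise ValueError("dmax_guess must be positive")
    q, i, s = c.q, c.intensity, c.sigma
    w = np.where(s > 0, 1.0 / s, 0.0)
    if not np.any(w > 0):
        w = np.ones_like(q)
    w = np.where(w > 0, w, np.max(w))

    candidates = np.linspace(candidate_span[0] * dmax_guess,
                             candidate_span[1] * dmax_guess, n_candidates)
    results = []
    for dmax in candidates:
        r = np.linspace(0.0, dmax, n_r)
        K = _ift_design(q, r) * w[:, None]
        y = i * w
        # second-difference operator on the full grid incl. zero endpoints
        m = n_r - 2
        D = np.zeros((m, m))
        idx = np.arange(m)
        D[idx, idx] = -2.0
        D[idx[:-1], idx[:-1] + 1] = 1.0
        D[idx[1:], idx[1:] - 1] = 1.0
        lam0 = np.linalg.norm(K) / max(np.linalg.norm(D), 1e-30)

        def solve(lam):
            A = np.vstack([K, lam * D])
            b = np.concatenate([y, np.zeros(m)])
            sol = lsq_linear(A, b, bounds=(0.0, np.inf), method="bvls",
                             max_iter=3 * m)
            res = float(np.sqrt(np.mean((K @ sol.x - y) ** 2)))
            return sol.x, res

        _, res_min = solve(1e-6 * lam0)
        best = None
        for lam in lam0 * np.logspace(-5, 0, 11):
            p_int, res = solve(lam)
            if res <= 1.05 * res_min:
                best = (p_int, res, lam)
            else:
                break
        if best is None:
            best = solve(1e-6 * lam0) + (1e-6 * lam0,)
        results.append((dmax, r, best[0], best[1]))

    res_best = min(r[3] for r in results)
    chosen = next(r for r in results if r[3] <= 1.05 * res_best)
    dmax, r, p_int, res = chosen
    p = np.zeros(n_r)
    p[1:-1] = p_int
    norm = np.trapezoid(p, r)
    if norm <= 0:
        raise ValueError("ill-conditioned p(r) inversion; try a larger dmax_guess")
    rg_real = float(np.sqrt(np.trapezoid(p * r**2, r) / (2.0 * norm)))
    return PofRResult(r=r, p=p, dmax=float(dmax), rg_real=rg_real, residual=res)
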