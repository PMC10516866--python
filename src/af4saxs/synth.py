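"""Forward simulation of AF4-SAXS fractograms with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a free-mRNA elution peak whose frames scatter as an unstructured random
  coil (Debye model, Rg ~ 25 nm, ~450 kDa),
* a lipoplex (LPX) peak whose frames scatter as compact polydisperse
  spheres (ensemble Rg growing with elution time, AF4 normal mode) with a
  single lamellar Bragg peak near q = 1 nm^-1 and a mid-q power-law
  envelope with a prescribed exponent,
* counting-like noise on the SAXS frames, matched UV 260 nm and MALS
  traces (inverse first-order Berry model), and a flat instrument
  background common to all frames.

Every true per-frame quantity is returned in a :class:`GroundTruth` so
downstream stages can be tested by parameter recovery.

Intensity scale convention: per frame, the envelope amplitude is
proportional to (mass concentration) x (particle mass) — as for forward
scattering of dilute particles — while the Bragg peak area is
proportional to the mass concentration alone, which is the constant
internal-stoichiometry premise the quantification stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Fractogram, ScatteringCurve
from .mals import DEFAULT_ANGLES, berry_records
from .units import N_A, NM3_TO_ML

__all__ = [
    "SizeLaw",
    "PopulationSpec",
    "GroundTruth",
    "coil_curve",
    "sphere_lamellar_curve",
    "simulate_fractogram",
    "reference_scenario",
    "REFERENCE_SCENARIO",
]

# 10% Gaussian radius polydispersity within an eluted fraction: small
# enough that a per-frame Guinier fit is meaningful, large enough to
# damp the sphere form-factor minima.
SPHERE_POLYDISPERSITY = 0.10

#: UV extinction of RNA at 260 nm [mL ug^-1 cm^-1] (A260 rule of thumb)
EPSILON_RNA = 0.025
UV_PATH_CM = 1.0

#: MALS optical constant x (mg/mL) -> Kc in the kDa unit convention
K_MALS = 1.0e-6

#: SAXS forward-intensity scale [counts per (mg/mL x kDa)]
K_SAXS = 50.0
#: Bragg peak area [counts nm^-1 per mg/mL of LPX material]
K_BRAGG = 5.8
#: UV turbidity [AU per (mg/mL x kDa)] of forward-scattering particles
K_TURB = 5.0e-11


@dataclass(frozen=True)
class SizeLaw:
    """Serializable elution-time -> true Rg [nm] mapping.

    ``constant``: rg0 everywhere.  ``linear``: rg0 at t0 ramping to rg1 at
    t1, clipped outside (monotone non-decreasing when rg1 >= rg0, the AF4
    normal mode where smaller particles elute first).
    """

    kind: str = "constant"
    rg0: float = 25.0
    rg1: float | None = None
    t0: float | None = None
    t1: float | None = None

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            return np.full_like(t, self.rg0, dtype=float)
        if self.kind == "linear":
            frac = np.clip((t - self.t0) / (self.t1 - self.t0), 0.0, 1.0)
            return self.rg0 + (self.rg1 - self.rg0) * frac
        raise ValueError(f"unknown size law {self.kind!r}")

    @property
    def monotone_non_decreasing(self) -> bool:
        return self.kind == "constant" or self.rg1 >= self.rg0


@dataclass(frozen=True)
class PopulationSpec:
    """Ground-truth description of one eluting species."""

    kind: str                      # 'coil' | 'sphere_lamellar' | 'globular'
    elution_center: float          # min
    elution_width: float           # Gaussian sigma [min]
    total_mass_conc: float         # mg/mL injected-equivalent
    size_law: SizeLaw
    bragg: tuple[float, float, float] | None = None   # (qc, w, relative amp)
    porod_exponent: float | None = None
    mw_true: float | None = None   # kDa (coil/globular)

    def __post_init__(self):
        if self.kind not in ("coil", "sphere_lamellar", "globular"):
            raise ValueError(f"unknown population kind {self.kind!r}")
        if self.elution_width <= 0:
            raise ValueError("elution_width must be positive")
        if self.total_mass_conc <= 0:
            raise ValueError("total_mass_conc must be positive")
        if self.porod_exponent is not None and not 2.5 < self.porod_exponent <= 4.2:
            raise ValueError("porod_exponent must lie in (2.5, 4.2]")
        if self.kind == "sphere_lamellar" and not self.size_law.monotone_non_decreasing:
            raise ValueError("sphere_lamellar size law must be monotone non-decreasing")


def _debye(u):
    """Debye coil function 2/u^2 (u - 1 + e^-u) with a stable small-u series."""
    u = np.asarray(u, dtype=float)
    small = u < 1e-6
    safe = np.where(small, 1.0, u)
    val = 2.0 / safe**2 * (safe - 1.0 + np.exp(-safe))
    return np.where(small, 1.0 - u / 3.0, val)


def coil_curve(q: np.ndarray, rg: float, i0: float,
               label: str = "coil") -> ScatteringCurve:
    """Noiseless Debye random-coil curve I(q) = i0 * D((q Rg)^2)."""
    if rg <= 0:
        raise ValueError("rg must be positive")
    q = np.asarray(q, dtype=float)
    i = i0 * _debye((q * rg) ** 2)
    return ScatteringCurve(q, i, np.zeros_like(q), label=label)


def _sphere_p(u):
    """Normalized solid-sphere form factor [3 (sin u - u cos u)/u^3]^2."""
    u = np.asarray(u, dtype=float)
    small = u < 1e-4
    safe = np.where(small, 1.0, u)
    amp = 3.0 * (np.sin(safe) - safe * np.cos(safe)) / safe**3
    amp = np.where(small, 1.0 - u**2 / 10.0, amp)
    return amp**2


def _poly_radii(r_mean: float, n: int = 61):
    """Gauss-Legendre nodes/weights for a Gaussian radius distribution
    truncated at +-3 sigma (sigma = SPHERE_POLYDISPERSITY * r_mean)."""
    sig = SPHERE_POLYDISPERSITY * r_mean
    x, w = np.polynomial.legendre.leggauss(n)
    r = r_mean + 3.0 * sig * x
    pdf = np.exp(-0.5 * ((r - r_mean) / sig) ** 2)
    return r, w * pdf


def _apparent_rg_factor() -> float:
    """Scattering-weighted apparent Rg of the polydisperse sphere ensemble,
    relative to the Rg of the mean-radius sphere (depends only on the
    relative polydispersity)."""
    r, w = _poly_radii(1.0)
    return float(np.sqrt(np.sum(w * r**8) / np.sum(w * r**6)))


_RG_APP_FACTOR = _apparent_rg_factor()


def _poly_sphere(q: np.ndarray, r_mean: float) -> np.ndarray:
    """Intensity-weighted polydisperse sphere form factor, normalized to 1
    at q -> 0.  The node count tracks q_max * sigma so the oscillatory
    radius integral stays resolved for large particles."""
    sig = SPHERE_POLYDISPERSITY * r_mean
    n = max(61, int(np.ceil(8.0 * np.max(q) * sig)))
    r, w = _poly_radii(r_mean, n)
    w6 = w * r**6
    p = _sphere_p(np.outer(q, r))
    return (p @ w6) / np.sum(w6)


def sphere_curve(q: np.ndarray, radius: float, i0: float,
                 label: str = "sphere") -> ScatteringCurve:
    """Noiseless monodisperse solid-sphere curve (oracle fixture):
    I(q) = i0 * [3 (sin qR - qR cos qR)/(qR)^3]^2."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    q = np.asarray(q, dtype=float)
    i = i0 * _sphere_p(q * radius)
    return ScatteringCurve(q, i, np.zeros_like(q), label=label)


def _guinier_porod(q: np.ndarray, rg: float, x: float) -> np.ndarray:
    """Smooth empirical envelope: Guinier at low q crossing over to a
    q^-x power law, with value and slope continuous at the crossover."""
    q1 = np.sqrt(1.5 * x) / rg
    d = np.exp(-q1**2 * rg**2 / 3.0) * q1**x
    return np.where(q <= q1, np.exp(-(q**2) * rg**2 / 3.0), d * q ** (-x))


def _bragg_term(q: np.ndarray, qc: float, w: float, area: float) -> np.ndarray:
    return (2.0 * area / np.pi) * w / (4.0 * (q - qc) ** 2 + w**2)


def sphere_lamellar_curve(q: np.ndarray, rg: float, i0: float,
                          bragg: tuple[float, float, float] | None,
                          porod_x: float = 3.63,
                          label: str = "sphere_lamellar") -> ScatteringCurve:
    """Compact-particle curve: polydisperse-sphere form factor whose mid-q
    envelope decays as q^-porod_x, plus an optional Lorentzian Bragg peak.

    ``rg`` is the ensemble (scattering-weighted) radius of gyration: the
    mean sphere radius is chosen so a Guinier fit of the noiseless curve
    returns ``rg``.  The envelope exponent is imposed by construction:
    the sphere average is multiplied by the ratio of a Guinier/power-law
    envelope with exponent ``porod_x`` (at ``rg``) to the ensemble's own
    q^-4 envelope, which preserves the low-q Guinier region exactly and
    keeps the damped sphere oscillations.  ``bragg`` is (qc, w, amp) with
    amp mapping to the Lorentzian peak area in curve units; the curve
    integral is proportional to ``i0`` at fixed shape parameters.
    """
    if rg <= 0:
        raise ValueError("rg must be positive")
    q = np.asarray(q, dtype=float)
    if bragg is not None:
        qc = bragg[0]
        if not q[0] < qc < q[-1]:
            raise ValueError("Bragg position qc outside the q-grid")
    rg_app = rg                      # ensemble Rg requested
    r_mean = np.sqrt(5.0 / 3.0) * rg / _RG_APP_FACTOR
    env = _guinier_porod(q, rg, porod_x) / _guinier_porod(q, rg_app, 4.0)
    i = i0 * _poly_sphere(q, r_mean) * env
    if bragg is not None:
        qc, w, amp = bragg
        i = i + _bragg_term(q, qc, w, amp)
    return ScatteringCurve(q, i, np.zeros_like(q), label=label)


@dataclass(frozen=True)
class GroundTruth:
    """Every true per-frame quantity behind a simulated fractogram."""

    frame_times: np.ndarray                  # min
    populations: tuple[PopulationSpec, ...]
    conc: np.ndarray                         # (n_pop, n_frames) mg/mL per frame
    rg: np.ndarray                           # (n_pop, n_frames) nm
    mw: np.ndarray                           # (n_pop, n_frames) kDa
    bragg_area: np.ndarray                   # (n_pop, n_frames) curve units
    kc: np.ndarray                           # Kc per frame (total, kDa units)
    uv_true: np.ndarray                      # noiseless UV [AU]
    noise_scale: float
    noise_seed: int
    background: np.ndarray                   # instrument background I(q)
    k_bragg: float = K_BRAGG
    epsilon_rna: float = EPSILON_RNA

    def population_index(self, kind: str) -> int:
        for i, p in enumerate(self.populations):
            if p.kind == kind:
                return i
        raise KeyError(kind)


def _lpx_particle_mw_kda(rg: float, rho: float = 1.11) -> float:
    """Particle molar mass [kDa] of a solid sphere with ensemble Rg."""
    r = np.sqrt(5.0 / 3.0) * rg
    m_g = (4.0 / 3.0) * np.pi * r**3 * NM3_TO_ML * rho
    return m_g * N_A * 1e-3   # g -> Da -> kDa


def simulate_fractogram(populations, q, frame_times, noise_seed: int = 0,
                        noise_scale: float = 0.01,
                        background_level: float = 0.2,
                        angles=DEFAULT_ANGLES,
                        mals_noise: float = 0.01) -> tuple[Fractogram, GroundTruth]:
    """Simulate a multi-detector AF4-SAXS run.

    Per frame and population the mass concentration follows a Gaussian
    elution profile normalized so its trapezoid integral over time equals
    ``total_mass_conc``.  SAXS frames are the concentration-weighted sum
    of the population curves plus Gaussian noise of sd
    ``noise_scale * sqrt(I)``; UV is Beer-Lambert absorbance of the RNA
    content plus a turbidity term proportional to forward light
    scattering; MALS records follow the inverse Berry relation at the
    detector angles with ``mals_noise`` relative noise.
    """
    populations = tuple(populations)
    if not populations:
        raise ValueError("need at least one population")
    q = np.asarray(q, dtype=float)
    t = np.asarray(frame_times, dtype=float)
    if len(t) < 8:
        raise ValueError("need at least 8 frames")
    rng = np.random.default_rng(noise_seed)
    n_pop, n_fr = len(populations), len(t)

    conc = np.zeros((n_pop, n_fr))
    rg = np.zeros((n_pop, n_fr))
    mw = np.zeros((n_pop, n_fr))
    bragg_area = np.zeros((n_pop, n_fr))
    for i, pop in enumerate(populations):
        prof = np.exp(-0.5 * ((t - pop.elution_center) / pop.elution_width) ** 2)
        # elution bands have finite support; an unbounded Gaussian tail of a
        # ~1e6 kDa particle population would dominate light scattering far
        # from its own peak
        prof[np.abs(t - pop.elution_center) > 4.0 * pop.elution_width] = 0.0
        conc[i] = pop.total_mass_conc * prof / np.trapezoid(prof, t)
        rg[i] = pop.size_law(t)
        if pop.kind == "coil":
            mw[i] = pop.mw_true
        elif pop.kind == "globular":
            mw[i] = pop.mw_true
        else:
            mw[i] = [_lpx_particle_mw_kda(r) for r in rg[i]]

    background = background_level * (1.0 + np.exp(-q / 0.5))

    frames = []
    uv_true = np.zeros(n_fr)
    mals_records = []
    ls_forward = np.zeros((n_pop, n_fr))   # c * MW, tracks forward scattering
    f_rna_lpx = 330.0 / 1335.0   # RNA mass fraction of the reference LPX
    for j in range(n_fr):
        i_tot = background.copy()
        for i, pop in enumerate(populations):
            c = conc[i, j]
            if c <= 0:
                continue
            i0 = K_SAXS * c * mw[i, j]     # forward intensity ~ c * MW
            if pop.kind == "coil":
                i_tot = i_tot + coil_curve(q, rg[i, j], i0).intensity
                uv_true[j] += EPSILON_RNA * 1e3 * UV_PATH_CM * c
            elif pop.kind == "globular":
                i_tot = i_tot + sphere_lamellar_curve(
                    q, rg[i, j], i0, bragg=None, porod_x=4.0
                ).intensity
            else:
                qc, w, amp_rel = pop.bragg if pop.bragg else (None, None, 0.0)
                area = K_BRAGG * c * amp_rel if pop.bragg else 0.0
                bragg_area[i, j] = area
                br = (qc, w, area) if pop.bragg else None
                i_tot = i_tot + sphere_lamellar_curve(
                    q, rg[i, j], i0, bragg=br,
                    porod_x=pop.porod_exponent or 3.63,
                ).intensity
                ls_forward[i, j] = c * mw[i, j]
                uv_true[j] += EPSILON_RNA * 1e3 * UV_PATH_CM * c * f_rna_lpx
        if noise_scale > 0:
            sd = noise_scale * np.sqrt(np.maximum(i_tot, 0.0))
            i_noisy = i_tot + rng.normal(0.0, 1.0, size=len(q)) * sd
        else:
            sd = np.zeros_like(q)
            i_noisy = i_tot
        frames.append(ScatteringCurve(q, i_noisy, sd, label=f"frame {j}"))

        # MALS: Rayleigh ratios add over co-eluting populations
        r_sum = np.zeros(len(angles))
        for i, pop in enumerate(populations):
            c = conc[i, j]
            if c <= 0:
                continue
            rec = berry_records(mw[i, j], rg[i, j], K_MALS * c, angles)
            r_sum = r_sum + rec[:, 1]
        if mals_noise > 0 and r_sum.max() > 0:
            r_sum = r_sum * (1.0 + mals_noise * rng.normal(size=len(angles)))
        mals_records.append(np.column_stack([np.asarray(angles, float), r_sum]))

    # UV turbidity of particles tracks forward light scattering
    turb = K_TURB * ls_forward.sum(axis=0)
    uv_true = uv_true + turb
    uv = uv_true.copy()
    if noise_scale > 0:
        uv = uv + 0.002 * uv.max() * rng.normal(size=n_fr)

    fr = Fractogram(
        frame_times=t,
        saxs_frames=tuple(frames),
        uv_260=uv,
        mals=tuple(mals_records),
        metadata={"exposure_s": 1.0, "flow_rate_ml_min": 0.5},
    )
    gt = GroundTruth(
        frame_times=t, populations=populations, conc=conc, rg=rg, mw=mw,
        bragg_area=bragg_area, kc=K_MALS * conc.sum(axis=0), uv_true=uv_true,
        noise_scale=noise_scale, noise_seed=noise_seed, background=background,
    )
    return fr, gt


#: the reference study conditions: free mRNA coil (Rg 25 nm, 450 kDa,
#: 0.045 mg/mL, eluting around 18 min) followed by a lipoplex population
#: (0.425 mg/mL, ensemble Rg ramping 80 -> 470 nm over 30-55 min, Bragg
#: peak at qc = 1.047 nm^-1 i.e. d = 6.0 nm, envelope exponent 3.63).
REFERENCE_SCENARIO = dict(
    q=np.linspace(0.02, 2.0, 400),
    frame_times=np.arange(0.0, 65.0, 0.25),
    populations=(
        PopulationSpec(
            kind="coil", elution_center=18.0, elution_width=1.5,
            total_mass_conc=0.045, size_law=SizeLaw("constant", rg0=25.0),
            mw_true=450.0,
        ),
        PopulationSpec(
            kind="sphere_lamellar", elution_center=40.0, elution_width=4.5,
            total_mass_conc=0.425,
            size_law=SizeLaw("linear", rg0=80.0, rg1=470.0, t0=30.0, t1=55.0),
            bragg=(1.047, 0.08, 1.0), porod_exponent=3.63,
        ),
    ),
)


def reference_scenario(noise_seed: int = 0, noise_scale: float = 0.01,
                        **overrides) -> tuple[Fractogram, GroundTruth]:
    """Simulate the reference two-population study conditions."""
    kw = dict(REFERENCE_SCENARIO)
    kw.update(overrides)
    return simulate_fractogram(
        kw["populations"], kw["q"], kw["frame_times"],
        noise_seed=noise_seed, noise_scale=noise_scale,
    )
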