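"""Reading and writing scattering curves, fractograms and formulation configs.

On-disk dialects:

* scattering curve: whitespace-separated ASCII ``.dat`` with 2 or 3 columns
  (q, I[, sigma]) and ``#`` comment/header lines — the de-facto beamline
  reduction format.  q is taken as nm^-1 unless a header line mentions an
  inverse-Angstrom unit (``1/A``, ``A^-1``, ``Å``), in which case q is
  multiplied by 10 on read.
* fractogram: a directory of per-frame ``.dat`` files plus a manifest table
  (columns ``file, time_min, uv_260``) and a long-format MALS table
  (columns ``frame, angle_deg, rayleigh``).
* formulation parameters: a YAML mapping; omitted keys fall back to the
  defaults of the reference lipoplex formulation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScatteringCurve",
    "Fractogram",
    "FormulationParams",
    "CurveParseError",
    "read_curve",
    "write_curve",
    "read_fractogram",
    "write_fractogram",
    "load_formulation",
]


class CurveParseError(ValueError):
    """Raised when a curve file cannot be parsed into (q, I, sigma)."""


@dataclass(frozen=True)
class ScatteringCurve:
    """One reduced 1D SAXS profile I(q).

    Attributes
    ----------
    q : ndarray
        Momentum transfer [nm^-1], strictly increasing, all > 0.
    intensity : ndarray
        I(q) in arbitrary units, linear in concentration.
    sigma : ndarray
        1-sigma uncertainty of I(q), same units, elementwise >= 0.
    label : str
        Free-text provenance.
    sigma_imputed : bool
        True when sigma was filled in as sqrt(I) because the source had
        only two columns.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    label: str = ""
    sigma_imputed: bool = False

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "sigma", s)
        if not (q.ndim == i.ndim == s.ndim == 1):
            raise ValueError("q, intensity, sigma must be 1-D")
        if not (len(q) == len(i) == len(s)):
            raise ValueError("q, intensity, sigma must have equal length")
        if len(q) < 8:
            raise ValueError("curve needs at least 8 points")
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if np.any(s < 0):
            raise ValueError("sigma must be non-negative")

    def __len__(self) -> int:
        return len(self.q)

    def window(self, q_lo: float, q_hi: float) -> "ScatteringCurve":
        """Sub-curve restricted to q in [q_lo, q_hi]."""
        m = (self.q >= q_lo) & (self.q <= q_hi)
        if m.sum() < 8:
            # relax the 8-point floor for windows by padding validation:
            # windows are working objects; keep invariant by raising instead
            raise ValueError("window contains fewer than 8 points")
        return replace(self, q=self.q[m], intensity=self.intensity[m], sigma=self.sigma[m])

    def scaled(self, k: float) -> "ScatteringCurve":
        return replace(self, intensity=k * self.intensity, sigma=abs(k) * self.sigma)


@dataclass(frozen=True)
class Fractogram:
    """Aligned per-frame detector series over elution time.

    ``saxs_frames`` all share one q-grid; ``uv_260`` and ``mals`` are
    parallel to ``frame_times``.  ``mals[i]`` is an (n_angles, 2) array of
    (angle [deg], excess Rayleigh ratio) rows, possibly empty.
    """

    frame_times: np.ndarray
    saxs_frames: tuple[ScatteringCurve, ...]
    uv_260: np.ndarray
    mals: tuple[np.ndarray, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.frame_times, dtype=float)
        uv = np.asarray(self.uv_260, dtype=float)
        object.__setattr__(self, "frame_times", t)
        object.__setattr__(self, "uv_260", uv)
        object.__setattr__(self, "saxs_frames", tuple(self.saxs_frames))
        object.__setattr__(self, "mals", tuple(np.asarray(m, dtype=float) for m in self.mals))
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        n = len(t)
        if len(self.saxs_frames) != n or len(uv) != n:
            raise ValueError("detector traces must match frame_times length")
        if self.mals and len(self.mals) != n:
            raise ValueError("mals records must match frame_times length")
        q0 = self.saxs_frames[0].q
        for fr in self.saxs_frames[1:]:
            if len(fr.q) != len(q0) or not np.array_equal(fr.q, q0):
                raise ValueError("all saxs_frames must share an identical q-grid")

    @property
    def q(self) -> np.ndarray:
        return self.saxs_frames[0].q

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    def intensity_matrix(self) -> np.ndarray:
        """(n_frames, n_q) intensity array."""
        return np.vstack([f.intensity for f in self.saxs_frames])

    def sigma_matrix(self) -> np.ndarray:
        return np.vstack([f.sigma for f in self.saxs_frames])


#: reference lipoplex formulation: DOTMA/DOPE 2:1 liposomes complexed with
#: mRNA at DOTMA:nucleotide charge ratio 0.65, 0.15 mg/mL total mRNA.
FORMULATION_DEFAULTS = dict(
    c_rna_total=0.15,        # mg/mL
    charge_ratio=0.65,       # DOTMA+ : nucleotide-
    mw_nucleotide=330.0,     # Da, average charged nucleotide
    mw_dotma=635.0,          # Da, DOTMA cation
    mw_dope=740.0,           # Da, zwitterionic DOPE
    dotma_dope_molar_ratio=2.0,
    rho_rna=1.68,            # g/mL
    rho_lipid=1.0,           # g/mL
    n_nucleotide=1200,       # nucleotides per mRNA copy
)


@dataclass(frozen=True)
class FormulationParams:
    """Stoichiometry and density constants of the lipoplex formulation."""

    c_rna_total: float = FORMULATION_DEFAULTS["c_rna_total"]
    charge_ratio: float = FORMULATION_DEFAULTS["charge_ratio"]
    mw_nucleotide: float = FORMULATION_DEFAULTS["mw_nucleotide"]
    mw_dotma: float = FORMULATION_DEFAULTS["mw_dotma"]
    mw_dope: float = FORMULATION_DEFAULTS["mw_dope"]
    dotma_dope_molar_ratio: float = FORMULATION_DEFAULTS["dotma_dope_molar_ratio"]
    rho_rna: float = FORMULATION_DEFAULTS["rho_rna"]
    rho_lipid: float = FORMULATION_DEFAULTS["rho_lipid"]
    n_nucleotide: int = FORMULATION_DEFAULTS["n_nucleotide"]

    def __post_init__(self):
        for name in (
            "c_rna_total", "mw_nucleotide", "mw_dotma", "mw_dope",
            "dotma_dope_molar_ratio", "rho_rna", "rho_lipid", "n_nucleotide",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.charge_ratio <= 1:
            raise ValueError("charge_ratio must be in (0, 1]")


_ANGSTROM_RE = re.compile(r"(1/A|A\^?-1|Å|angstrom)", re.IGNORECASE)


def read_curve(path: str | Path) -> ScatteringCurve:
    """Read a 2- or 3-column ASCII ``.dat`` scattering curve.

    Header/comment lines (leading ``#`` or non-numeric) are skipped.  If a
    header declares inverse-Angstrom q units, q is converted to nm^-1.
    Missing sigma is imputed as sqrt(max(I, eps)) with ``sigma_imputed``
    set and a warning.
    """
    path = Path(path)
    angstrom = False
    rows: list[tuple[float, ...]] = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if _ANGSTROM_RE.search(stripped):
                    angstrom = True
                continue
            parts = stripped.split()
            try:
                vals = tuple(float(p) for p in parts)
            except ValueError:
                if rows:
                    raise CurveParseError(
                        f"{path}: malformed numeric row at line {lineno}: {stripped!r}"
                    ) from None
                # pre-data header without '#'
                if _ANGSTROM_RE.search(stripped):
                    angstrom = True
                continue
            if len(vals) not in (2, 3):
                raise CurveParseError(
                    f"{path}: expected 2 or 3 columns at line {lineno}, got {len(vals)}"
                )
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise CurveParseError(
                    f"{path}: inconsistent column count at line {lineno}"
                )
            rows.append(vals)
    if len(rows) < 8:
        raise CurveParseError(f"{path}: needs at least 8 data rows, found {len(rows)}")
    arr = np.asarray(rows, dtype=float)
    q = arr[:, 0]
    if angstrom:
        q = q * 10.0
    intensity = arr[:, 1]
    imputed = False
    if arr.shape[1] == 3:
        sigma = arr[:, 2]
    else:
        warnings.warn(f"{path}: no sigma column; imputing sqrt(I)", stacklevel=2)
        sigma = np.sqrt(np.maximum(intensity, 1e-12))
        imputed = True
    if np.any(np.diff(q) <= 0):
        raise ValueError(f"{path}: q not strictly increasing")
    return ScatteringCurve(q, intensity, sigma, label=path.name, sigma_imputed=imputed)


def write_curve(curve: ScatteringCurve, path: str | Path) -> None:
    """Write a curve as 3-column ASCII with a provenance header."""
    header = f"q[1/nm] I(q) sigma | {curve.label}"
    np.savetxt(
        Path(path),
        np.column_stack([curve.q, curve.intensity, curve.sigma]),
        header=header,
        fmt="%.8e",
    )


def read_fractogram(directory: str | Path, manifest: str | Path,
                    mals_table: str | Path | None = None,
                    grid_rtol: float = 0.01) -> Fractogram:
    """Assemble a :class:`Fractogram` from per-frame files and a manifest.

    The manifest is a whitespace/comma table with columns
    ``file, time_min, uv_260``; rows are sorted by time.  Frames whose
    q-grid differs from the first frame's by < ``grid_rtol`` per point are
    linearly interpolated onto the first grid; larger deviations raise.
    """
    directory = Path(directory)
    man = pd.read_csv(manifest, sep=None, engine="python", comment="#")
    required = {"file", "time_min", "uv_260"}
    if not required.issubset(man.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    man = man.sort_values("time_min", kind="stable").reset_index(drop=True)
    curves = []
    for fname in man["file"]:
        fpath = directory / str(fname)
        if not fpath.exists():
            raise FileNotFoundError(f"frame file missing: {fpath}")
        curves.append(read_curve(fpath))
    q0 = curves[0].q
    aligned = []
    for c in curves:
        if np.array_equal(c.q, q0):
            aligned.append(c)
            continue
        if len(c.q) != len(q0) or np.any(np.abs(c.q - q0) > grid_rtol * q0):
            raise ValueError(f"q-grid of {c.label} deviates beyond tolerance")
        aligned.append(
            ScatteringCurve(
                q0,
                np.interp(q0, c.q, c.intensity),
                np.interp(q0, c.q, c.sigma),
                label=c.label,
                sigma_imputed=c.sigma_imputed,
            )
        )
    mals: tuple[np.ndarray, ...] = ()
    if mals_table is not None:
        tab = pd.read_csv(mals_table, sep=None, engine="python", comment="#")
        need = {"frame", "angle_deg", "rayleigh"}
        if not need.issubset(tab.columns):
            raise ValueError(f"MALS table must have columns {sorted(need)}")
        recs = []
        for i in range(len(man)):
            sub = tab[tab["frame"] == i]
            recs.append(sub[["angle_deg", "rayleigh"]].to_numpy(dtype=float))
        mals = tuple(recs)
    return Fractogram(
        frame_times=man["time_min"].to_numpy(dtype=float),
        saxs_frames=tuple(aligned),
        uv_260=man["uv_260"].to_numpy(dtype=float),
        mals=mals,
    )


def write_fractogram(fr: Fractogram, directory: str | Path,
                     prefix: str = "frame") -> tuple[Path, Path | None]:
    """Write per-frame .dat files, a manifest, and (if present) a MALS table.

    Returns (manifest_path, mals_path or None).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (t, curve, uv) in enumerate(zip(fr.frame_times, fr.saxs_frames, fr.uv_260)):
        fname = f"{prefix}_{i:04d}.dat"
        write_curve(curve, directory / fname)
        rows.append((fname, t, uv))
    man = pd.DataFrame(rows, columns=["file", "time_min", "uv_260"])
    manifest_path = directory / "manifest.csv"
    man.to_csv(manifest_path, index=False)
    mals_path = None
    if fr.mals:
        recs = []
        for i, m in enumerate(fr.mals):
            for angle, ray in np.atleast_2d(m) if m.size else []:
                recs.append((i, angle, ray))
        mals_path = directory / "mals.csv"
        pd.DataFrame(recs, columns=["frame", "angle_deg", "rayleigh"]).to_csv(
            mals_path, index=False
        )
    return manifest_path, mals_path


def load_formulation(path: str | Path | None = None, **overrides) -> FormulationParams:
    """Load formulation parameters from YAML, filling defaults when omitted."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("formulation config must be a mapping")
        unknown = set(loaded) - set(FORMULATION_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown formulation keys: {sorted(unknown)}")
        values.update(loaded)
    values.update(overrides)
    return FormulationParams(**values)
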