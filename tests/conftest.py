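"""Shared fixtures: the reference two-population scenario is simulated and
analysed once per session and reused by the recovery tests."""

from __future__ import annotations

import numpy as np
import pytest

from af4saxs import bragg as B
from af4saxs import mals as M
from af4saxs import processing as P
from af4saxs import quantify as Q
from af4saxs import synth as S
from af4saxs.io import FormulationParams


@pytest.fixture(scope="session")
def formulation():
    return FormulationParams()


@pytest.fixture(scope="session")
def stoich(formulation):
    return Q.derive_stoichiometry(formulation)


@pytest.fixture(scope="session")
def ref_run(formulation, stoich):
    """Simulate the reference scenario (seed 1, 1% noise) and run the full
    analysis chain in memory; returns every intermediate."""
    fr, gt = S.reference_scenario(noise_seed=1, noise_scale=0.01)
    buf = P.select_buffer_frames(fr, "auto")
    fr2 = P.subtract_buffer(fr, buf)
    uv = P.elution_trace(fr2, "uv")
    sax = P.elution_trace(fr2, "saxs_integrated")
    rna_idx = P.peak_frames(uv, 0.02, time_window=(10.0, 25.0))
    c_free = Q.free_rna_from_uv(uv, rna_idx)
    c_total, free_frac = Q.c_lpx_total(formulation, stoich, c_free)
    lpx_idx = P.peak_frames(sax, 0.02, time_window=(26.0, 62.0))
    btab, area = B.bragg_series(fr2, lpx_idx, baseline="power_law")
    c_dif = Q.normalize_bragg_area(area, lpx_idx, c_total)
    msr = M.mals_series(fr2, gt.kc)
    table = Q.size_resolved_table(c_dif, msr["rg"].to_numpy(), stoich, formulation)
    return dict(
        fr=fr, gt=gt, fr2=fr2, buf=buf, uv=uv, sax=sax, rna_idx=rna_idx,
        c_free=c_free, c_total=c_total, free_frac=free_frac, lpx_idx=lpx_idx,
        btab=btab, area=area, c_dif=c_dif, msr=msr, table=table,
    )


@pytest.fixture(scope="session")
def ref_run_noiseless():
    """Noiseless reference scenario with the Bragg-area route applied;
    isolates systematic fidelity from counting noise."""
    fr, gt = S.reference_scenario(noise_seed=0, noise_scale=0.0)
    buf = P.select_buffer_frames(fr, "auto")
    fr2 = P.subtract_buffer(fr, buf)
    i = gt.population_index("sphere_lamellar")
    lpx_idx = np.flatnonzero(gt.conc[i] > 0)
    btab, area = B.bragg_series(fr2, lpx_idx, baseline="power_law")
    return dict(fr=fr, gt=gt, fr2=fr2, lpx_idx=lpx_idx, btab=btab, area=area)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
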