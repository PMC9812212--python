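"""Self-contained desk-scale experiments composed from the library modules.

These recipes drive the full pipeline end to end on synthetic crystals:

* the rotation-substep study - how the merging statistic R_merge of an
  ideal (static, symmetric) supercell depends on the angular substep used
  to accumulate each oscillation frame;
* the displacement/B-factor consistency check - a Gaussian-displacement
  ensemble must attenuate Bragg intensities by exp(-2 B s^2) with
  B = 8 pi^2 sigma^2, tying the diffraction engine to the fluctuation
  metric;
* the cross-engine comparison - direct summation vs the gridded-FFT path
  on the same toy crystal.

They are used by the test suite and the reproduction script; parameters
default to sizes that run in minutes on one CPU core.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .bragg import integrate_series, predict_reflections, r_merge
from .crystal_model import SpaceGroup, UnitCell
from .fixtures import make_gaussian_ensemble, make_point_lattice, \
    make_toy_asu_crystal
from .geometry import DetectorGeometry, RotationSeries, detector_q_grid
from .photograph import fft_photograph, simulate_frame, simulate_series

__all__ = [
    "delta_omega_rmerge_ladder",
    "debye_waller_recovery",
    "cross_engine_rms",
]


def _windows_mask(table, shape, half: int) -> np.ndarray:
    """Union of integration windows around predicted spots (per series)."""
    mask = np.zeros(shape, dtype=bool)
    n_slow, n_fast = shape
    for _, row in table.iterrows():
        cf, cs = int(round(row["fast"])), int(round(row["slow"]))
        mask[max(cs - half, 0):cs + half + 1,
             max(cf - half, 0):cf + half + 1] = True
    return mask


def delta_omega_rmerge_ladder(substeps=(8.0, 0.8, 0.08), total_range=64.0,
                              n_cells=(2, 24, 24), spacing=10.0,
                              frame_width=8.0, d_min=1.35,
                              box=2, annulus=5) -> dict[float, float]:
    """R_merge of a static ideal supercell for each rotation substep.

    The crystal is a point-scatterer supercell, thin along the rotation
    axis so that rocking-curve widths (~(1/L)/|q_yz|, here ~0.2-1 degree)
    fall between the coarsest and finest substeps of the ladder
    (frame width, /10, /100).  Frames are simulated only inside the
    integration windows of the predicted reflections; merging uses the
    orthorhombic sign-flip orbit (P222 + Friedel), whose members observed
    inside one wedge have mirror-related Ewald crossings and therefore
    identical converged rocking integrals (no Lorentz correction needed).
    The wedge must span several tens of degrees: the mirror mates of a
    reflection cross up to ~2 asin(lambda q^2 / 2 |q_yz|) apart.
    """
    crystal = make_point_lattice(*n_cells, spacing)
    cell = UnitCell(spacing, spacing, spacing)
    sg = SpaceGroup.from_symbol("P222")
    geom = DetectorGeometry(1.54, 30.0, 1.8, 72, 72, (36.0, 36.0))
    out = {}
    for sub in substeps:
        series = RotationSeries(start=0.0, frame_width=frame_width,
                                substep=sub, total_range=total_range)
        table = predict_reflections(cell, None, series, geom, d_min=d_min)
        photos = []
        for f in range(series.n_frames):
            # simulate only the integration windows of this frame's spots
            mask = _windows_mask(table[table["frame"] == f], geom.shape,
                                 annulus + 1)
            photos.append(simulate_frame(crystal, geom, series, None, f,
                                         mask=mask))
        table = integrate_series(photos, table, box=box, annulus=annulus)
        out[sub] = r_merge(table[~table["partial"]], sg, friedel=True)
    return out


def debye_waller_recovery(sigma=0.3, n_frames=256, n_cells=8, spacing=3.0,
                          s_max=0.4, seed=0) -> tuple[float, float]:
    """Recover B from the Bragg attenuation of a Gaussian ensemble.

    Returns ``(b_recovered, b_expected)`` where b_expected = 8 pi^2 sigma^2
    and b_recovered comes from regressing log(I_ensemble / (n * I_static))
    against s^2 over low-order Bragg peaks (slope = -2B for harmonic
    isotropic displacements).
    """
    base = make_point_lattice(n_cells, n_cells, n_cells, spacing)
    ens = make_gaussian_ensemble(base, sigma, n_frames, seed=seed)
    peaks = [np.array(hkl) / spacing
             for hkl in itertools.product(range(3), repeat=3)
             if any(hkl)]
    peaks = [g for g in peaks if np.linalg.norm(g) / 2.0 <= s_max]
    from .photograph import intensity_at_q

    qs = np.array(peaks)
    i_static = intensity_at_q(base, qs)
    i_ens = intensity_at_q(ens, qs)
    s2 = (np.linalg.norm(qs, axis=1) / 2.0) ** 2
    log_ratio = np.log(i_ens / (n_frames * i_static))
    slope = np.polyfit(s2, log_ratio, 1)[0]
    b_recovered = -slope / 2.0
    return float(b_recovered), 8.0 * math.pi ** 2 * sigma ** 2


def cross_engine_rms(seed=7, grid_spacing=0.5) -> float:
    """Relative RMS deviation between the direct and gridded-FFT engines.

    Simulates one oscillation frame of a ~640-atom symmetric toy crystal
    with both engines and returns RMS(I_fft - I_direct)/RMS(I_direct) over
    the pixels valid for the gridded engine's resolution.
    """
    sg = SpaceGroup.from_symbol("P43212")
    cell = UnitCell(20.0, 20.0, 14.0)
    crystal = make_toy_asu_crystal(sg, cell, (2, 2, 1), seed=seed)
    geom = DetectorGeometry(1.54, 40.0, 0.5, 60, 50, (30.0, 25.0))
    series = RotationSeries(frame_width=1.0, substep=0.5, total_range=1.0)
    direct = simulate_frame(crystal, geom, series, None, 0)
    gridded = fft_photograph(crystal, geom, series, 0,
                             grid_spacing=grid_spacing)
    sel = gridded.mask
    num = np.sqrt(np.mean((gridded.data[sel] - direct.data[sel]) ** 2))
    den = np.sqrt(np.mean(direct.data[sel] ** 2))
    return float(num / den)
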