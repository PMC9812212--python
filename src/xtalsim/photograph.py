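"""Diffraction-photograph simulation by direct summation of secondary wavelets.

Every atom j of a snapshot is a source of a secondary wavelet; the complex
amplitude reaching detector pixel p is

    A_total(p) = sum_j occ_j * f_j(s(p); B_j) * exp(i * 2*pi * r_j . (k - k'(p)))

with f_j the tabulated atomic scattering factor and the wavevector
convention |k| = |k'| = 1/lambda.  Within one snapshot the wavelets add as
complex numbers; across rotation substeps and across snapshots the
contributions add by intensity |A_total|^2, imitating the accumulation of
exposure on a real detector (phases are not registered).  All atoms enter
the sum - protein, solvent, ions, and hydrogens.

A second engine grids each snapshot's scatterers, FFTs the grid, and reads
the amplitudes off the Ewald sphere by Gaussian-kernel interpolation; it is
mathematically equivalent at the resolution supported by the grid and is
used for cross-validation of the direct sum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.fft import ifftn, next_fast_len

from .crystal_model import Ensemble, LabeledAtomSet
from .geometry import (
    DetectorGeometry,
    RotationSeries,
    as_orientation,
    axis_rotation,
    detector_q_grid,
    frame_plan,
    pixel_to_kprime,
)
from .scattering import ScatteringTable, load_table

__all__ = [
    "Photograph",
    "wavelet_phase",
    "amplitude_at_pixel",
    "simulate_frame",
    "simulate_series",
    "intensity_at_q",
    "fft_photograph",
]

log = logging.getLogger("xtalsim")

#: upper bound on the number of (atom x pixel) phase-matrix elements held at
#: once; the per-pixel sum is evaluated in atom blocks under this budget.
PHASE_BLOCK_ELEMS = 4_000_000


@dataclass
class Photograph:
    """One simulated oscillation frame: intensity raster plus provenance."""

    data: np.ndarray  # (n_slow, n_fast) intensities, arbitrary units
    frame_index: int
    angle_range: tuple[float, float]  # degrees covered by the frame
    n_snapshots: int
    mask: np.ndarray  # True = simulated pixel

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape must equal raster shape")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("intensities must be finite and non-negative")


def wavelet_phase(r, k, kprime) -> np.ndarray:
    """Phase 2*pi * r.(k - k') of the wavelet from an atom at r, in radians."""
    r = np.asarray(r, dtype=float)
    q = np.asarray(k, dtype=float) - np.asarray(kprime, dtype=float)
    return 2.0 * np.pi * (r @ q if r.ndim == 1 and q.ndim == 1
                          else np.sum(r * q, axis=-1))


def _ensure_ensemble(obj) -> Ensemble:
    if isinstance(obj, Ensemble):
        return obj
    if isinstance(obj, LabeledAtomSet):
        return Ensemble(obj, obj.xyz[None])
    raise TypeError("expected LabeledAtomSet or Ensemble")


def _element_groups(snapshot: LabeledAtomSet):
    order = {}
    for i, el in enumerate(snapshot.element):
        order.setdefault(str(el), []).append(i)
    return {el: np.array(idx) for el, idx in order.items()}


def _amplitude(xyz, occ, b, groups, q, s, table, honor_b) -> np.ndarray:
    """Complex A over arbitrary q points; q (..., 3), s (...) matching."""
    qf = q.reshape(-1, 3)
    sf = s.reshape(-1)
    npix = len(qf)
    out = np.zeros(npix, dtype=complex)
    s2 = sf * sf
    for el, idx in groups.items():
        f_el = table[el].evaluate(sf)
        sub = xyz[idx]
        occ_el = occ[idx]
        b_el = b[idx]
        block = max(1, PHASE_BLOCK_ELEMS // max(npix, 1))
        acc = np.zeros(npix, dtype=complex)
        for lo in range(0, len(sub), block):
            chunk = slice(lo, lo + block)
            phase = np.exp(2j * np.pi * (sub[chunk] @ qf.T))
            w = occ_el[chunk, None]
            if honor_b:
                w = w * np.exp(-np.outer(b_el[chunk], s2))
            acc += (w * phase).sum(axis=0)
        out += f_el * acc
    return out.reshape(s.shape)


def amplitude_at_pixel(snapshot: LabeledAtomSet, p, geom: DetectorGeometry,
                       honor_b: bool = False,
                       table: ScatteringTable | None = None) -> np.ndarray:
    """A_total at pixel(s) p = (fast, slow) for one snapshot, in electrons.

    By default every atom scatters with B = 0 (the ensemble itself carries
    the motion); ``honor_b=True`` applies the per-atom B factors instead.
    """
    table = table or load_table()
    p = np.asarray(p, dtype=float)
    kprime = pixel_to_kprime(p, geom)
    q = geom.k_in - kprime
    s = np.linalg.norm(q, axis=-1) / 2.0
    a = _amplitude(snapshot.xyz, snapshot.occupancy, snapshot.b_factor,
                   _element_groups(snapshot), np.atleast_2d(q),
                   np.atleast_1d(s), table, honor_b)
    return a if p.ndim > 1 else a[()] if a.shape == () else a.reshape(())


def _frame_entry(series: RotationSeries, frame_index: int):
    plan = dict(frame_plan(series))
    if frame_index not in plan:
        raise IndexError(
            f"frame {frame_index} outside plan (0..{series.n_frames - 1})")
    return plan[frame_index]


def simulate_frame(ensemble, geom: DetectorGeometry, series: RotationSeries,
                   orientation=None, frame_index: int = 0, *,
                   mask: np.ndarray | None = None, honor_b: bool = False,
                   table: ScatteringTable | None = None) -> Photograph:
    """One oscillation frame: sum of |A_total|^2 over snapshots and substeps.

    The orientation matrix is applied to all snapshot coordinates first;
    each substep then rotates the crystal about the series axis to the
    substep midpoint angle.  Masked pixels are zeroed and flagged invalid.
    """
    ens = _ensure_ensemble(ensemble)
    if ens.n_frames == 0:
        raise ValueError("empty ensemble")
    table = table or load_table()
    u = np.eye(3) if orientation is None else as_orientation(orientation)
    angles = _frame_entry(series, frame_index)
    q, s = detector_q_grid(geom)
    valid = np.ones(geom.shape, dtype=bool) if mask is None else \
        np.asarray(mask, dtype=bool)
    qv, sv = q[valid], s[valid]  # only simulated pixels are evaluated
    groups = _element_groups(ens.base)
    occ, b = ens.base.occupancy, ens.base.b_factor
    acc = np.zeros(len(qv))
    for isnap in range(ens.n_frames):
        oriented = ens.coords[isnap] @ u.T
        for ang in angles:
            rot = axis_rotation(series.axis, ang)
            a = _amplitude(oriented @ rot.T, occ, b, groups, qv, sv, table,
                           honor_b)
            acc += np.abs(a) ** 2
    intensity = np.zeros(geom.shape)
    intensity[valid] = acc
    log.info("frame %d: %d snapshots x %d substeps done",
             frame_index, ens.n_frames, len(angles))
    return Photograph(intensity, frame_index, series.frame_interval(frame_index),
                      ens.n_frames, valid)


def simulate_series(ensemble, geom: DetectorGeometry, series: RotationSeries,
                    orientation=None, **kwargs) -> list[Photograph]:
    """Apply simulate_frame over the whole frame plan."""
    return [
        simulate_frame(ensemble, geom, series, orientation, f, **kwargs)
        for f, _ in frame_plan(series)
    ]


def intensity_at_q(ensemble, q, table: ScatteringTable | None = None,
                   honor_b: bool = False) -> np.ndarray:
    """Detector-free probe: sum over snapshots of |sum_j f_j exp(2pi i r.q)|^2."""
    ens = _ensure_ensemble(ensemble)
    table = table or load_table()
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    qa = np.atleast_2d(q)
    s = np.linalg.norm(qa, axis=-1) / 2.0
    groups = _element_groups(ens.base)
    out = np.zeros(len(qa))
    for isnap in range(ens.n_frames):
        a = _amplitude(ens.coords[isnap], ens.base.occupancy,
                       ens.base.b_factor, groups, qa, s, table, honor_b)
        out += np.abs(a) ** 2
    return float(out[0]) if single else out


# --------------------------------------------------------------------------
# gridded-FFT engine

_SPREAD_W = 5  # kernel half-width, grid cells (both domains)


def _gaussian_grid_transform(xyz, weights, h, n, origin, s_x, s_q, dq):
    """Accumulate Gaussian-spread scatterers and FFT to the reciprocal grid.

    Returns G such that  sum_k g_q(q - k) G[k]  approximates
    sum_j w_j exp(2 pi i q . r_j)  after deconvolution of the spreading
    kernel (done by the caller); grid point m maps to k = (m - n/2) * dq.
    """
    offs = np.arange(-_SPREAD_W, _SPREAD_W + 1)
    rho = np.zeros(tuple(n))
    chunk = 2000
    for lo in range(0, len(xyz), chunk):
        sub = (xyz[lo:lo + chunk] - origin) / h + np.asarray(n) / 2.0
        w = weights[lo:lo + chunk]
        i0 = np.rint(sub).astype(int)
        # separable per-axis Gaussian weights
        wxyz = [np.exp(-((sub[:, d, None] - (i0[:, d, None] + offs[None, :]))
                         * h[d]) ** 2 / (2.0 * s_x[d] ** 2)) for d in range(3)]
        wall = (w[:, None, None, None]
                * wxyz[0][:, :, None, None]
                * wxyz[1][:, None, :, None]
                * wxyz[2][:, None, None, :])
        idx = ((i0[:, 0, None, None, None] + offs[:, None, None]) * n[1]
               + (i0[:, 1, None, None, None] + offs[None, :, None])) * n[2] \
            + (i0[:, 2, None, None, None] + offs[None, None, :])
        rho += np.bincount(idx.ravel(), weights=wall.ravel(),
                           minlength=n[0] * n[1] * n[2]).reshape(tuple(n))
    # deconvolution for the q-domain interpolation kernel (step b)
    for d in range(3):
        x = (np.arange(n[d]) - n[d] // 2) * h[d]
        psi = dq[d] / (s_q[d] * math.sqrt(2 * math.pi)) \
            * np.exp(2 * np.pi ** 2 * s_q[d] ** 2 * x ** 2)
        rho *= psi.reshape([-1 if k == d else 1 for k in range(3)])
    # G[m] = sum_i rho[i] exp(+2 pi i (m - n/2).(i - n/2)/n)
    signs = [(-1.0) ** np.arange(n[d]) for d in range(3)]
    for d in range(3):
        rho = rho * signs[d].reshape([-1 if k == d else 1 for k in range(3)])
    g = ifftn(rho) * np.prod(n)
    for d in range(3):
        g = g * signs[d].reshape([-1 if k == d else 1 for k in range(3)])
    const = (-1.0) ** (sum(int(nd) // 2 for nd in n))
    return g * const


def _interp_reciprocal(g, qpts, n, dq, s_q):
    """Gaussian-kernel interpolation of G at arbitrary q points."""
    offs = np.arange(-_SPREAD_W, _SPREAD_W + 1)
    m = qpts / dq + np.asarray(n) // 2
    m0 = np.rint(m).astype(int)
    if np.any(m0 - _SPREAD_W < 0) or np.any(m0 + _SPREAD_W >= np.asarray(n)):
        raise ValueError("q point outside reciprocal grid support")
    w = [np.exp(-((m[:, d, None] - (m0[:, d, None] + offs[None, :]))
                  * dq[d]) ** 2 / (2.0 * s_q[d] ** 2)) for d in range(3)]
    gf = g.reshape(-1)
    out = np.zeros(len(qpts), dtype=complex)
    for a in range(2 * _SPREAD_W + 1):
        for b in range(2 * _SPREAD_W + 1):
            base = ((m0[:, 0] + offs[a]) * n[1] + (m0[:, 1] + offs[b])) * n[2] \
                + m0[:, 2]
            block = gf[base[:, None] + offs[None, :]]
            out += w[0][:, a] * w[1][:, b] * (block * w[2]).sum(axis=1)
    return out


class _GriddedSnapshot:
    """Per-element reciprocal grids of one snapshot, reusable across substeps."""

    def __init__(self, snapshot: LabeledAtomSet, grid_spacing: float,
                 q_max: float):
        if np.any(snapshot.b_factor != 0):
            raise ValueError(
                "the gridded engine supports only B = 0 atoms; "
                "use the direct engine to honor per-atom B factors")
        h_target = min(0.75 * grid_spacing, 1.0 / (4.0 * q_max))
        lo = snapshot.xyz.min(axis=0)
        hi = snapshot.xyz.max(axis=0)
        self.center = 0.5 * (lo + hi)
        # keep the crystal within the central third of the box regardless of
        # grid spacing, so the interpolation-alias floor is h-independent
        extent = np.maximum(hi - lo, 10.0 * h_target)
        length = 3.0 * extent + 4.0 * _SPREAD_W * h_target
        self.n = np.array([next_fast_len(int(math.ceil(L / h_target)) + 1)
                           for L in length])
        self.n += self.n % 2  # even sizes keep the phase constant real
        self.h = length / self.n
        self.dq = 1.0 / (self.n * self.h)
        # kernel widths balance truncation against periodic-image aliasing
        # for the +/-_SPREAD_W window and the 3x box padding
        self.s_x = self.h.copy()
        self.s_q = 1.0 * self.dq
        self.grids = {}
        groups = _element_groups(snapshot)
        for el, idx in groups.items():
            self.grids[el] = _gaussian_grid_transform(
                snapshot.xyz[idx], snapshot.occupancy[idx], self.h, self.n,
                self.center, self.s_x, self.s_q, self.dq)

    def amplitude(self, qpts: np.ndarray, s: np.ndarray, table) -> np.ndarray:
        # spreading-kernel deconvolution (step a)
        decon = np.exp(2 * np.pi ** 2 * (qpts ** 2 * self.s_x ** 2).sum(axis=1))
        decon *= np.prod(self.h / (self.s_x * math.sqrt(2 * math.pi)))
        out = np.zeros(len(qpts), dtype=complex)
        for el, g in self.grids.items():
            f_el = table[el].evaluate(s)
            out += f_el * _interp_reciprocal(g, qpts, self.n, self.dq, self.s_q)
        # restore the phase of the box-centering shift
        return out * decon * np.exp(2j * np.pi * (qpts @ self.center))


def fft_photograph(ensemble, geom: DetectorGeometry, series: RotationSeries,
                   frame_index: int = 0, grid_spacing: float = 0.4,
                   orientation=None, *, d_min: float | None = None,
                   mask: np.ndarray | None = None,
                   table: ScatteringTable | None = None,
                   snapshot_average: str = "intensity") -> Photograph:
    """FFT-engine counterpart of simulate_frame.

    Each snapshot is spread onto a real-space grid (Gaussian kernels
    consistent with the tabulated form factors applied in reciprocal
    space), transformed once, and evaluated on the Ewald sphere for every
    substep.  Pixels beyond the resolution supported by the grid
    (d < 3 * grid_spacing) are masked invalid.

    ``snapshot_average="intensity"`` accumulates |A|^2 per snapshot exactly
    like the direct engine; ``"amplitude"`` averages the complex amplitudes
    (equivalently, the densities) over snapshots before squaring, which
    suppresses the diffuse component of a dynamic ensemble.
    """
    ens = _ensure_ensemble(ensemble)
    table = table or load_table()
    if snapshot_average not in ("intensity", "amplitude"):
        raise ValueError("snapshot_average must be 'intensity' or 'amplitude'")
    implied_d_min = 3.0 * grid_spacing
    if d_min is not None and grid_spacing > d_min / 3.0 + 1e-12:
        raise ValueError(
            f"grid spacing {grid_spacing} A too coarse for d_min {d_min} A "
            f"(supports only d >= {implied_d_min:.3f} A)")
    d_eff = d_min if d_min is not None else implied_d_min
    u = np.eye(3) if orientation is None else as_orientation(orientation)
    angles = _frame_entry(series, frame_index)
    q, s = detector_q_grid(geom)
    valid = np.ones(geom.shape, dtype=bool) if mask is None else \
        np.asarray(mask, dtype=bool).copy()
    with np.errstate(divide="ignore"):
        valid &= s <= 1.0 / (2.0 * d_eff)
    qf = q[valid]
    sf = s[valid]
    q_max = 1.0 / d_eff
    intensity = np.zeros(geom.shape)
    amp_sum = [np.zeros(len(qf), dtype=complex) for _ in angles]
    for isnap in range(ens.n_frames):
        snap = ens.frame(isnap)
        gridded = _GriddedSnapshot(snap, grid_spacing, q_max)
        for ia, ang in enumerate(angles):
            rot = axis_rotation(series.axis, ang)
            # active rotation of the crystal == evaluating at (R U)^T q
            q_cr = qf @ (rot @ u)
            a = gridded.amplitude(q_cr, sf, table)
            if snapshot_average == "intensity":
                vals = np.zeros(geom.shape)
                vals[valid] = np.abs(a) ** 2
                intensity += vals
            else:
                amp_sum[ia] += a
    if snapshot_average == "amplitude":
        for acc in amp_sum:
            vals = np.zeros(geom.shape)
            vals[valid] = np.abs(acc / ens.n_frames) ** 2
            intensity += vals
    log.info("fft frame %d: %d snapshots x %d substeps done",
             frame_index, ens.n_frames, len(angles))
    return Photograph(intensity, frame_index, series.frame_interval(frame_index),
                      ens.n_frames, valid)
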