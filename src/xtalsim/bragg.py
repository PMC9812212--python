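"""Bragg-reflection prediction, spot integration and symmetry merging.

A desk-scale data-reduction path: reflections are predicted from the Ewald
condition during the rotation series, integrated on the simulated
photographs by simple summation with a median-annulus background, merged
over the point-group orbit, and summarized by R_merge

    R_merge = sum_h sum_i |I_hi - <I_h>| / sum_h sum_i I_hi

over groups with multiplicity >= 2.  No Lorentz/polarization corrections,
no profile fitting, no inter-frame scaling: the statistic is meant for
relative comparisons (e.g. of rotation-substep choices), not for matching
full data-reduction programs.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .crystal_model import SpaceGroup, UnitCell
from .geometry import DetectorGeometry, RotationSeries, as_orientation
from .photograph import Photograph

__all__ = [
    "predict_reflections",
    "integrate_spot",
    "integrate_series",
    "symmetry_equivalents",
    "canonical_hkl",
    "r_merge",
]

log = logging.getLogger("xtalsim")

TABLE_COLUMNS = ["h", "k", "l", "frame", "angle", "fast", "slow", "d",
                 "intensity", "background", "partial"]


def predict_reflections(cell: UnitCell, orientation, series: RotationSeries,
                        geom: DetectorGeometry, d_min: float,
                        boundary_tol: float = 0.1) -> pd.DataFrame:
    """Predict where and at which rotation angle reflections hit the detector.

    For every (h,k,l) with d >= d_min the rotation angles at which the
    reciprocal-lattice vector crosses the Ewald sphere (|k - G| = 1/lambda)
    are solved in closed form for the x-axis rotation; in-raster crossings
    inside the series range are kept and assigned to the frame containing
    the crossing angle.  ``boundary_tol`` (degrees) flags crossings close to
    a frame boundary as partial.
    """
    lam = geom.wavelength
    if d_min <= lam / 2.0:
        raise ValueError("d_min must exceed lambda/2 (back-scattering limit)")
    if tuple(np.round(series.axis, 9)) != (1.0, 0.0, 0.0):
        raise ValueError("the predictor assumes rotation about the lab x axis")
    u = as_orientation(orientation) if orientation is not None else np.eye(3)
    bmat = u @ cell.reciprocal_matrix  # columns a*, b*, c* in the lab frame
    qmax = 1.0 / d_min
    hmax = [int(math.ceil(qmax / np.linalg.norm(bmat[:, i]))) for i in range(3)]
    hh, kk, ll = np.meshgrid(*[np.arange(-m, m + 1) for m in hmax],
                             indexing="ij")
    hkl = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    g0 = hkl @ bmat.T
    norm = np.linalg.norm(g0, axis=1)
    keep = norm <= qmax
    hkl, g0, norm = hkl[keep], g0[keep], norm[keep]

    e = lam * norm ** 2 / 2.0
    rho = np.hypot(g0[:, 1], g0[:, 2])
    phi = np.arctan2(g0[:, 2], g0[:, 1])
    cross = rho > 0
    ratio = np.where(cross, np.clip(e / np.where(cross, rho, 1.0), -1, 1), 2.0)
    reachable = cross & (e <= rho)
    base = np.arcsin(np.where(reachable, ratio, 0.0))

    start, rng = series.start, series.total_range
    cf, cs = geom.beam_center
    rows = []
    for branch in (base, np.pi - base):
        omega = np.degrees(branch - phi)
        omega = start + np.mod(omega - start, 360.0)
        ok = reachable & (omega < start + rng - 1e-12)
        if not np.any(ok):
            continue
        w = np.radians(omega[ok])
        gy, gz = g0[ok, 1], g0[ok, 2]
        g_rot = np.stack([
            g0[ok, 0],
            gy * np.cos(w) - gz * np.sin(w),
            gy * np.sin(w) + gz * np.cos(w),
        ], axis=1)
        kprime = np.array([0.0, 0.0, 1.0 / lam]) - g_rot
        vis = kprime[:, 2] > 1e-9
        fast = cf + kprime[:, 0] / kprime[:, 2] * geom.distance / geom.pixel_size
        slow = cs + kprime[:, 1] / kprime[:, 2] * geom.distance / geom.pixel_size
        inside = vis & (fast >= 0) & (fast <= geom.n_fast - 1) & \
            (slow >= 0) & (slow <= geom.n_slow - 1)
        idx = np.flatnonzero(ok)[inside]
        om = omega[ok][inside]
        off = (om - start) / series.frame_width
        frame = np.floor(off).astype(int)
        near_edge = np.minimum(off - frame, frame + 1 - off) \
            * series.frame_width < boundary_tol
        for j, i0 in enumerate(idx):
            rows.append({
                "h": int(hkl[i0, 0]), "k": int(hkl[i0, 1]), "l": int(hkl[i0, 2]),
                "frame": int(frame[j]), "angle": float(om[j]),
                "fast": float(fast[inside][j]), "slow": float(slow[inside][j]),
                "d": float(1.0 / norm[i0]),
                "intensity": np.nan, "background": np.nan,
                "partial": bool(near_edge[j]),
            })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def integrate_spot(photo: Photograph, pos, box: int = 3,
                   annulus: int = 6) -> tuple[float, float, bool]:
    """Summation integration at pixel pos = (fast, slow).

    intensity = sum(box window) - n_box * median(annulus);
    background = median(annulus).  The partial flag is set when the window
    is clipped by the raster edge or touches masked pixels.
    """
    n_slow, n_fast = photo.data.shape
    cf, cs = int(round(pos[0])), int(round(pos[1]))
    partial = False
    f_lo, f_hi = cf - box, cf + box
    s_lo, s_hi = cs - box, cs + box
    af_lo, af_hi = cf - annulus, cf + annulus
    as_lo, as_hi = cs - annulus, cs + annulus
    if f_lo < 0 or s_lo < 0 or f_hi >= n_fast or s_hi >= n_slow:
        partial = True
    cf_lo, cf_hi = max(f_lo, 0), min(f_hi, n_fast - 1)
    cs_lo, cs_hi = max(s_lo, 0), min(s_hi, n_slow - 1)
    window = photo.data[cs_lo:cs_hi + 1, cf_lo:cf_hi + 1]
    wmask = photo.mask[cs_lo:cs_hi + 1, cf_lo:cf_hi + 1]
    if not wmask.all():
        partial = True
    n_box = window.size
    bf_lo, bf_hi = max(af_lo, 0), min(af_hi, n_fast - 1)
    bs_lo, bs_hi = max(as_lo, 0), min(as_hi, n_slow - 1)
    ann = photo.data[bs_lo:bs_hi + 1, bf_lo:bf_hi + 1].copy()
    annmask = photo.mask[bs_lo:bs_hi + 1, bf_lo:bf_hi + 1].copy()
    annmask[(cs_lo - bs_lo):(cs_hi - bs_lo + 1),
            (cf_lo - bf_lo):(cf_hi - bf_lo + 1)] = False
    bgvals = ann[annmask]
    background = float(np.median(bgvals)) if bgvals.size else 0.0
    intensity = float(window.sum() - n_box * background)
    return intensity, background, partial


def integrate_series(photos: list[Photograph], table: pd.DataFrame,
                     box: int = 3, annulus: int = 6) -> pd.DataFrame:
    """Fill the intensity/background columns of a predicted reflection table."""
    out = table.copy()
    for i, row in out.iterrows():
        photo = photos[int(row["frame"])]
        inten, bg, clipped = integrate_spot(photo, (row["fast"], row["slow"]),
                                            box, annulus)
        out.at[i, "intensity"] = inten
        out.at[i, "background"] = bg
        if clipped:
            out.at[i, "partial"] = True
    return out


def symmetry_equivalents(hkl, sg: SpaceGroup,
                         friedel: bool = True) -> list[tuple[int, int, int]]:
    """Orbit of (h,k,l) under the point group (optionally with Friedel mates)."""
    h = np.asarray(hkl, dtype=int)
    orbit = {tuple(int(x) for x in h @ rot)
             for rot in sg.point_group_rotations()}
    if friedel:
        orbit |= {tuple(-x for x in m) for m in orbit}
    return sorted(orbit, reverse=True)


def canonical_hkl(hkl, sg: SpaceGroup, friedel: bool = True):
    """Lexicographically largest orbit member - the merging key."""
    return symmetry_equivalents(hkl, sg, friedel)[0]


def r_merge(table: pd.DataFrame, sg: SpaceGroup, friedel: bool = True,
            include_partial: bool = True) -> float:
    """Merging R of symmetry-equivalent integrated intensities.

    Groups are keyed by the canonical orbit representative; only groups
    with multiplicity >= 2 enter the sums.  Negative intensities are kept
    as integrated; groups whose intensity sum is non-positive are dropped
    (logged), since they cannot contribute a meaningful precision term.
    """
    df = table.dropna(subset=["intensity"])
    if not include_partial:
        df = df[~df["partial"].astype(bool)]
    if df.empty:
        raise ValueError("no integrated reflections")
    keys = [canonical_hkl((r.h, r.k, r.l), sg, friedel)
            for r in df.itertuples()]
    df = df.assign(_key=keys)
    grouped = df.groupby("_key")["intensity"]
    sizes = grouped.transform("size")
    multi = df[sizes >= 2]
    if multi.empty:
        raise ValueError("R_merge undefined: no group has multiplicity >= 2")
    gm = multi.groupby("_key")["intensity"]
    sums = gm.sum()
    dropped = int((sums <= 0).sum())
    if dropped:
        log.info("r_merge: dropping %d group(s) with non-positive sum", dropped)
    keep = sums[sums > 0].index
    multi = multi[multi["_key"].isin(keep)]
    if multi.empty:
        raise ValueError("R_merge undefined: all groups had non-positive sums")
    means = multi.groupby("_key")["intensity"].transform("mean")
    num = float(np.abs(multi["intensity"] - means).sum())
    den = float(multi["intensity"].sum())
    return num / den
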