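"""Deterministic synthetic inputs for tests, examples and benchmarks.

Everything here regenerates byte-identically from (parameters, seed): toy
point-scatterer lattices with closed-form interference patterns, a compact
pseudo-peptide asymmetric unit expanded into symmetric crystals,
Gaussian-displacement ensembles standing in for MD snapshots (isotropic
harmonic motion - the statistical model behind the B-factor/fluctuation
relation), and self-consistent binary detector-file templates for
grafting tests.  No fixture emulates the sequence, chemistry or force
field of a real protein; see the methods note for what that implies.
"""

from __future__ import annotations

import struct

import numpy as np

from .crystal_model import (
    Ensemble,
    LabeledAtomSet,
    SpaceGroup,
    SupercellSpec,
    UnitCell,
    build_supercell,
    expand_asymmetric_unit,
    solvate_random,
)

__all__ = [
    "make_point_lattice",
    "make_toy_asu_crystal",
    "make_gaussian_ensemble",
    "make_template_image",
]


def make_point_lattice(n_a: int, n_b: int, n_c: int, spacing: float,
                       element: str = "C") -> LabeledAtomSet:
    """Single-element scatterers on an n_a x n_b x n_c grid, B = 0.

    The carrier for closed-form finite-lattice interference tests
    (sin^2(N pi u)/sin^2(pi u) along a line, N^2 |F_cell|^2 factorization
    at reciprocal-lattice points).
    """
    if min(n_a, n_b, n_c) < 1:
        raise ValueError("lattice counts must be >= 1")
    ia, ib, ic = np.meshgrid(np.arange(n_a), np.arange(n_b), np.arange(n_c),
                             indexing="ij")
    xyz = spacing * np.stack([ia.ravel(), ib.ravel(), ic.ravel()], axis=1)
    n = len(xyz)
    return LabeledAtomSet.from_arrays(
        element=np.array([element] * n, dtype=object),
        xyz=xyz.astype(float),
        molecule=np.arange(n),
        resseq=np.arange(1, n + 1),
        cell=UnitCell(spacing, spacing, spacing),
        spacegroup_name="P1",
    )


#: elements drawn for the pseudo-peptide asu (all present in the shipped
#: scattering table)
_ASU_ELEMENTS = np.array(["C", "C", "C", "N", "O"], dtype=object)


def make_toy_asu_crystal(sg: SpaceGroup, cell: UnitCell, n_rep=(1, 1, 1),
                         n_atoms: int = 20, seed: int = 0,
                         n_waters: int = 0) -> LabeledAtomSet:
    """A compact random asymmetric unit, symmetry-expanded and replicated.

    The asu is a seeded cluster of ~20 light atoms inside a small ball
    near the cell origin (a stand-in for a tiny peptide), expanded by the
    space group into one cell and tiled into the requested supercell;
    optional random waters are added by rejection sampling.
    """
    rng = np.random.default_rng(seed)
    radius = 0.12 * min(cell.a, cell.b, cell.c)
    pts = []
    while len(pts) < n_atoms:
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) <= radius:
            pts.append(p)
    center = cell.orthogonalization @ np.array([0.125, 0.125, 0.125])
    xyz = np.array(pts) + center
    asu = LabeledAtomSet.from_arrays(
        element=_ASU_ELEMENTS[rng.integers(0, len(_ASU_ELEMENTS), n_atoms)],
        xyz=xyz,
        resseq=np.ones(n_atoms, dtype=int),
        molecule=np.zeros(n_atoms, dtype=int),
        cell=cell, spacegroup_name=sg.name,
    )
    one_cell = expand_asymmetric_unit(asu, sg, cell)
    spec = SupercellSpec(*n_rep, cell=cell, spacegroup=sg)
    crystal = build_supercell(one_cell, spec)
    if n_waters:
        box = np.diag(cell.orthogonalization) * np.array(n_rep)
        crystal = solvate_random(crystal, box, n_waters, min_dist=2.4,
                                 seed=seed + 1)
    return crystal


def make_gaussian_ensemble(base: LabeledAtomSet, sigma: float,
                           n_frames: int, seed: int = 0) -> Ensemble:
    """Snapshots displacing every atom by an isotropic 3-D Gaussian.

    ``sigma`` is the one-dimensional (per-axis) standard deviation in
    angstroms, so the expected r.m.s.f. per atom is sigma * sqrt(3) and
    the corresponding displacement parameter is B = 8 pi^2 sigma^2.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    disp = rng.normal(0.0, sigma, size=(n_frames, len(base), 3)) \
        if sigma > 0 else np.zeros((n_frames, len(base), 3))
    return Ensemble(base, base.xyz[None] + disp)


_TEMPLATE_MAGIC = b"XTALSIM_TEMPLATE"


def make_template_image(n_fast: int, n_slow: int, seed: int = 0,
                        mask_regions=None):
    """A synthetic detector file standing in for an experimental template.

    Returns ``(blob, descriptor, mask)``: the file bytes (dummy tagged
    header + little-endian uint16 data + trailer), the data-array
    descriptor ``(offset, length, dtype)``, and a boolean preserve mask
    built from the given ``(fast_lo, fast_hi, slow_lo, slow_hi)`` regions
    (e.g. beamstop or spacer rectangles).
    """
    rng = np.random.default_rng(seed)
    data = rng.integers(0, 1000, size=(n_slow, n_fast), dtype=np.uint16)
    header = _TEMPLATE_MAGIC + struct.pack("<III", n_fast, n_slow, seed)
    header = header.ljust(128, b"\x00")
    trailer = b"END_OF_TEMPLATE".ljust(32, b"\x00")
    blob = header + data.astype("<u2").tobytes() + trailer
    descriptor = (len(header), 2 * n_fast * n_slow, "<u2")
    mask = np.zeros((n_slow, n_fast), dtype=bool)
    for f_lo, f_hi, s_lo, s_hi in (mask_regions or []):
        mask[s_lo:s_hi, f_lo:f_hi] = True
    return blob, descriptor, mask
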