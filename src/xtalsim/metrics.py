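"""Ensemble-dynamics analysis: r.m.s.d./r.m.s.f., B factors, ordered waters.

Two alignment conventions are used throughout, matching how crystal-
simulation trajectories are compared with crystal structures:

* best fit - every protein copy in a snapshot is optimally superposed
  (rotation + translation, Kabsch) onto the reference molecule, so only
  internal deformation remains;
* lattice - the whole supercell is aligned to the reference supercell by
  center of mass only (no rotation), so rigid-body motion of molecules
  within the lattice is retained.

The isotropic-harmonic link between fluctuation amplitude and the
crystallographic displacement parameter is B = (8 pi^2 / 3) * rmsf^2.
Ordered waters are compared between two structures through conserved
water-protein hydrogen bonds (same protein partner atom, same
donor/acceptor capacity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from scipy.stats import pearsonr

from .crystal_model import Ensemble, LabeledAtomSet

__all__ = [
    "unwrap_periodic",
    "best_fit_rmsd",
    "lattice_rmsd",
    "rmsf",
    "b_from_rmsf",
    "rmsf_from_b",
    "b_profile",
    "b_profile_correlation",
    "HBondCriteria",
    "hbond",
    "match_ordered_waters",
    "WaterMatch",
]

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}
WATER_RESIDUES = {"HOH", "WAT"}


# --------------------------------------------------------------------------
# periodic-jump correction

def unwrap_periodic(ensemble: Ensemble, box) -> Ensemble:
    """Remove box-size jumps of molecule centers between consecutive frames.

    Whenever a molecule's center moves by more than half a box edge from
    one frame to the next, the integer box shift minimizing the
    displacement is applied to that molecule from that frame onward,
    making each molecular trajectory continuous.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    coords = ensemble.coords.copy()
    mols = ensemble.base.molecule
    for m in np.unique(mols):
        sel = mols == m
        raw_centers = ensemble.coords[:, sel].mean(axis=1)
        shift = np.zeros(3)
        prev = raw_centers[0]
        for t in range(1, ensemble.n_frames):
            jump = raw_centers[t] + shift * box - prev
            n = np.rint(jump / box)
            shift -= n
            coords[t, sel] += shift * box
            prev = raw_centers[t] + shift * box
    return Ensemble(ensemble.base, coords)


# --------------------------------------------------------------------------
# selections and molecule bookkeeping

def _selection_mask(atoms: LabeledAtomSet, selection) -> np.ndarray:
    if selection is None or selection == "all":
        return np.ones(len(atoms), dtype=bool)
    if isinstance(selection, str):
        if selection.upper() == "CA":
            return np.asarray([n == "CA" for n in atoms.name])
        if selection == "heavy":
            return atoms.element != "H"
        if selection in ("sidechain", "sidechain_heavy"):
            return np.asarray(
                [e != "H" and n not in BACKBONE_NAMES
                 and r not in WATER_RESIDUES
                 for e, n, r in zip(atoms.element, atoms.name, atoms.residue)])
        raise ValueError(f"unknown selection {selection!r}")
    return np.asarray(selection, dtype=bool)


def _molecule_blocks(atoms: LabeledAtomSet) -> list[np.ndarray]:
    return [np.flatnonzero(atoms.molecule == m)
            for m in np.unique(atoms.molecule)]


def _kabsch_rmsd(moving: np.ndarray, target: np.ndarray) -> float:
    mc = moving - moving.mean(axis=0)
    tc = target - target.mean(axis=0)
    rot, _ = Rotation.align_vectors(tc, mc)
    d = mc @ rot.as_matrix().T - tc
    return float(np.sqrt((d ** 2).sum() / len(d)))


def best_fit_rmsd(snapshot: LabeledAtomSet, reference: LabeledAtomSet,
                  selection=None) -> tuple[np.ndarray, float]:
    """Optimal-superposition r.m.s.d. of every molecule copy vs the reference.

    The reference is a single molecule; each molecule in the snapshot must
    carry the same selected-atom count, with correspondence by roster
    order.  Returns (per-molecule r.m.s.d., mean).
    """
    ref_mask = _selection_mask(reference, selection)
    ref = reference.xyz[ref_mask]
    snap_mask = _selection_mask(snapshot, selection)
    values = []
    for idx in _molecule_blocks(snapshot):
        pick = idx[snap_mask[idx]]
        if len(pick) == 0:
            continue
        if len(pick) != len(ref):
            raise ValueError(
                f"selected-atom count mismatch: copy has {len(pick)}, "
                f"reference has {len(ref)}")
        values.append(_kabsch_rmsd(snapshot.xyz[pick], ref))
    values = np.array(values)
    return values, float(values.mean())


def lattice_rmsd(snapshot: LabeledAtomSet, reference_supercell: LabeledAtomSet,
                 selection=None) -> float:
    """r.m.s.d. after aligning supercell centers of mass (no rotation)."""
    if len(snapshot) != len(reference_supercell):
        raise ValueError("snapshot and reference rosters differ in size")
    mask = _selection_mask(reference_supercell, selection)
    delta = snapshot.xyz.mean(axis=0) - reference_supercell.xyz.mean(axis=0)
    d = (snapshot.xyz - delta)[mask] - reference_supercell.xyz[mask]
    return float(np.sqrt((d ** 2).sum() / mask.sum()))


def rmsf(ensemble: Ensemble, reference: LabeledAtomSet, mode: str = "best-fit",
         selection=None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation over frames, pooled over copies.

    ``mode="best-fit"`` superposes every copy on the (single-molecule)
    reference in every frame; ``mode="lattice"`` aligns each whole frame to
    the reference supercell by center of mass only (apply unwrap_periodic
    first for wrapped trajectories).  Fluctuations are measured about the
    per-copy time mean and pooled over copies.
    """
    if ensemble.n_frames < 2:
        raise ValueError("r.m.s.f. needs at least two frames")
    if mode not in ("best-fit", "lattice"):
        raise ValueError("mode must be 'best-fit' or 'lattice'")
    snap_mask = _selection_mask(ensemble.base, selection)
    blocks = _molecule_blocks(ensemble.base)
    if mode == "best-fit":
        ref_mask = _selection_mask(reference, selection)
        ref = reference.xyz[ref_mask]
        refc = ref - ref.mean(axis=0)
        aligned = []  # (copies) of (frames, n_sel, 3)
        for idx in blocks:
            pick = idx[snap_mask[idx]]
            if len(pick) == 0:
                continue
            if len(pick) != len(refc):
                raise ValueError("selected-atom count mismatch with reference")
            traj = []
            for t in range(ensemble.n_frames):
                mv = ensemble.coords[t, pick]
                mvc = mv - mv.mean(axis=0)
                rot, _ = Rotation.align_vectors(refc, mvc)
                traj.append(mvc @ rot.as_matrix().T)
            aligned.append(np.array(traj))
        stacked = np.stack(aligned)  # (copies, frames, n, 3)
    else:
        delta = ensemble.coords.mean(axis=1, keepdims=True) \
            - reference.xyz.mean(axis=0)
        shifted = ensemble.coords - delta  # (frames, atoms, 3)
        per_copy = []
        n_sel = None
        for idx in blocks:
            pick = idx[snap_mask[idx]]
            if len(pick) == 0:
                continue
            if n_sel is None:
                n_sel = len(pick)
            if len(pick) != n_sel:
                raise ValueError("molecule copies carry unequal selections")
            per_copy.append(shifted[:, pick])
        stacked = np.stack(per_copy)
    mean = stacked.mean(axis=1, keepdims=True)  # per-copy time mean
    dev2 = ((stacked - mean) ** 2).sum(axis=-1)  # (copies, frames, n)
    return np.sqrt(dev2.mean(axis=(0, 1)))


# --------------------------------------------------------------------------
# B factors

_B_CONST = 8.0 * math.pi ** 2 / 3.0


def b_from_rmsf(value):
    """B = (8 pi^2 / 3) * rmsf^2, in A^2 for rmsf in A."""
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("r.m.s.f. must be >= 0")
    out = _B_CONST * value ** 2
    return float(out) if out.ndim == 0 else out

def rmsf_from_b(value):
    """Inverse of b_from_rmsf."""
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("B must be >= 0")
    out = np.sqrt(value / _B_CONST)
    return float(out) if out.ndim == 0 else out


def b_profile(atoms: LabeledAtomSet, selection: str = "CA") -> pd.Series:
    """Per-residue B-factor profile from the structure's B column.

    ``selection="CA"`` takes the C-alpha B factor; ``"sidechain"`` averages
    over side-chain heavy atoms of each residue.
    """
    mask = _selection_mask(atoms, "CA" if selection.upper() == "CA"
                           else "sidechain")
    df = pd.DataFrame({
        "resseq": atoms.resseq[mask],
        "b": atoms.b_factor[mask],
    })
    if df.empty:
        raise ValueError("selection matched no atoms")
    return df.groupby("resseq")["b"].mean()


def b_profile_correlation(p1, p2) -> float:
    """Pearson correlation of two aligned B-factor profiles."""
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be equal-length 1-D arrays")
    if len(a) < 3:
        raise ValueError("need at least 3 profile entries")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance profile")
    return float(pearsonr(a, b)[0])


# --------------------------------------------------------------------------
# hydrogen bonds and ordered waters

@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond test: D-A distance and D-H...A angle."""

    max_distance: float = 3.5  # A, |D - A| strictly less than this
    min_angle: float = 150.0  # degrees, angle at H strictly greater

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 < self.min_angle < 180.0:
            raise ValueError("angle cutoff must be in (0, 180)")


def hbond(donor, hydrogen, acceptor, crit: HBondCriteria = HBondCriteria()) -> bool:
    """True iff |D-A| < cutoff and the D-H...A angle at H exceeds the cutoff."""
    d = np.asarray(donor, dtype=float)
    h = np.asarray(hydrogen, dtype=float)
    a = np.asarray(acceptor, dtype=float)
    v1 = d - h
    v2 = a - h
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValueError("coincident atoms make the D-H...A angle undefined")
    if np.linalg.norm(d - a) >= crit.max_distance:
        return False
    angle = math.degrees(math.acos(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)))
    return angle > crit.min_angle


@dataclass
class WaterMatch:
    """Result of ordered-water comparison between two structures."""

    count: int
    mapping: dict  # water key in A -> water key in B
    generated_hydrogens: bool  # True when H positions had to be synthesized


_POLAR = {"N", "O", "S"}


def _water_partner_sets(atoms: LabeledAtomSet, crit: HBondCriteria):
    """For each water: the set of (protein partner atom, capacity) pairs.

    Capacity is the water's role: 'donor' when the water donates its H to a
    protein acceptor, 'acceptor' when a protein donor D-H points at the
    water oxygen.  Waters (or protein donors) lacking explicit hydrogens
    get an H placed 1.0 A along the donor->acceptor direction - a stand-in
    that reduces the angle criterion to the distance criterion for those
    bonds.
    """
    is_water = np.asarray([r in WATER_RESIDUES for r in atoms.residue])
    if not np.any(~is_water):
        raise ValueError("structure contains no protein atoms")
    water_o = np.flatnonzero(is_water & (atoms.element == "O"))
    prot = np.flatnonzero(~is_water)
    prot_polar = prot[np.isin(atoms.element[prot], list(_POLAR))]
    if len(prot_polar) == 0:
        raise ValueError("no polar protein atoms to hydrogen-bond to")
    prot_h = prot[atoms.element[prot] == "H"]
    tree = cKDTree(atoms.xyz[prot_polar])
    generated = False
    partners: dict = {}
    for o in water_o:
        wkey = (int(atoms.molecule[o]), int(atoms.resseq[o]))
        found = set()
        o_pos = atoms.xyz[o]
        near = tree.query_ball_point(o_pos, crit.max_distance)
        # the water's own hydrogens, if present
        own_h = np.flatnonzero((atoms.molecule == atoms.molecule[o])
                               & (atoms.element == "H"))
        for j in near:
            p = prot_polar[j]
            p_pos = atoms.xyz[p]
            pkey = (str(atoms.residue[p]), int(atoms.resseq[p]),
                    str(atoms.name[p]))
            # water as donor: O-H ... protein acceptor
            if len(own_h):
                ok = any(hbond(o_pos, atoms.xyz[hh], p_pos, crit)
                         for hh in own_h)
            else:
                generated = True
                ok = np.linalg.norm(p_pos - o_pos) < crit.max_distance
            if ok:
                found.add((pkey, "donor"))
            # water as acceptor: protein D-H ... O
            attached = [hh for hh in prot_h
                        if np.linalg.norm(atoms.xyz[hh] - p_pos) < 1.3]
            if attached:
                ok = any(hbond(p_pos, atoms.xyz[hh], o_pos, crit)
                         for hh in attached)
            elif len(prot_h) == 0:
                generated = True
                ok = np.linalg.norm(p_pos - o_pos) < crit.max_distance
            else:
                ok = False
            if ok:
                found.add((pkey, "acceptor"))
        if found:
            partners[wkey] = (found, o_pos)
    return partners, generated


def match_ordered_waters(struct_a: LabeledAtomSet, struct_b: LabeledAtomSet,
                         crit: HBondCriteria = HBondCriteria()) -> WaterMatch:
    """Count waters hydrogen-bonded identically in two structures.

    A water in A matches a water in B when they share at least one
    (protein partner atom, capacity) pair; assignment is greedy 1:1 by
    partner-overlap size, ties broken by O-O distance.
    """
    pa, gen_a = _water_partner_sets(struct_a, crit)
    pb, gen_b = _water_partner_sets(struct_b, crit)
    candidates = []
    for ka, (seta, posa) in pa.items():
        for kb, (setb, posb) in pb.items():
            overlap = len(seta & setb)
            if overlap:
                candidates.append(
                    (overlap, -float(np.linalg.norm(posa - posb)), ka, kb))
    candidates.sort(reverse=True)
    used_a, used_b = set(), set()
    mapping = {}
    for _, _, ka, kb in candidates:
        if ka in used_a or kb in used_b:
            continue
        used_a.add(ka)
        used_b.add(kb)
        mapping[ka] = kb
    return WaterMatch(len(mapping), mapping, gen_a or gen_b)
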