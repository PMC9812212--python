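"""Crystal construction: coordinates, symmetry expansion, supercells, solvent.

The pipeline mirrors how an explicit-crystal simulation box is set up: an
asymmetric unit read from PDB is expanded by the space-group operators into
one unit cell, the cell is replicated on the n_a x n_b x n_c lattice into a
finite supercell block (no periodic wrapping - the diffraction treatment
sums over an explicit finite crystal), and random solvent waters plus
neutralizing monatomic ions are added by rejection sampling.

Coordinates are Cartesian angstroms throughout; fractionalization happens
only inside the symmetry expansion, using the standard PDB orthogonalization
convention (a along x, b in the x-y plane).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "UnitCell",
    "SpaceGroup",
    "SupercellSpec",
    "LabeledAtomSet",
    "Ensemble",
    "read_structure",
    "write_structure",
    "expand_asymmetric_unit",
    "build_supercell",
    "solvate_random",
    "neutralize",
    "DEFAULT_CHARGE_SCHEME",
]


# --------------------------------------------------------------------------
# cell and symmetry types

@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters: lengths in angstroms, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    @property
    def orthogonalization(self) -> np.ndarray:
        """3x3 matrix whose columns are the cell vectors a, b, c (PDB frame)."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg, sg = math.cos(al), math.cos(be), math.cos(ga), math.sin(ga)
        v = math.sqrt(max(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg, 0.0))
        m = np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )
        if abs(np.linalg.det(m)) < 1e-9:
            raise ValueError("degenerate unit cell (singular orthogonalization)")
        return m

    @property
    def fractionalization(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization)

    @property
    def reciprocal_matrix(self) -> np.ndarray:
        """Columns are the reciprocal basis vectors a*, b*, c* in 1/A."""
        return np.linalg.inv(self.orthogonalization).T

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.orthogonalization))


# Operator triplet strings shipped as data.  P1 and P43212 cover the
# tetragonal lysozyme case; P222 is used for sign-flip merging orbits.
SYMMETRY_TRIPLETS: dict[str, tuple[str, ...]] = {
    "P1": ("x,y,z",),
    "P43212": (
        "x,y,z",
        "-x,-y,z+1/2",
        "-y+1/2,x+1/2,z+3/4",
        "y+1/2,-x+1/2,z+1/4",
        "-x+1/2,y+1/2,-z+3/4",
        "x+1/2,-y+1/2,-z+1/4",
        "y,x,-z",
        "-y,-x,-z+1/2",
    ),
    "P222": ("x,y,z", "-x,-y,z", "-x,y,-z", "x,-y,-z"),
}


def _parse_triplet(triplet: str) -> tuple[np.ndarray, np.ndarray]:
    op = gemmi.Op(triplet)
    rot = np.array(op.rot, dtype=float) / gemmi.Op.DEN
    tran = np.array(op.tran, dtype=float) / gemmi.Op.DEN
    return rot, tran


@dataclass(frozen=True)
class SpaceGroup:
    """A space group as an explicit closed list of fractional operators."""

    name: str
    rotations: np.ndarray  # (n, 3, 3)
    translations: np.ndarray  # (n, 3)

    @staticmethod
    def _canonical(symbol: str) -> str:
        return symbol.replace(" ", "").replace("_", "").upper().replace("P1211", "P21")

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroup":
        key = cls._canonical(symbol)
        if key in SYMMETRY_TRIPLETS:
            return cls.from_triplets(key, SYMMETRY_TRIPLETS[key])
        sg = gemmi.find_spacegroup_by_name(symbol)
        if sg is None:
            raise ValueError(f"unknown space group symbol {symbol!r}")
        return cls.from_triplets(
            cls._canonical(sg.hm), tuple(op.triplet() for op in sg.operations())
        )

    @classmethod
    def from_triplets(cls, name: str, triplets) -> "SpaceGroup":
        parsed = [_parse_triplet(t) for t in triplets]
        rot = np.array([p[0] for p in parsed])
        tran = np.array([p[1] for p in parsed])
        group = cls(name, rot, tran)
        group._check_closure()
        return group

    def __len__(self) -> int:
        return len(self.rotations)

    def _check_closure(self) -> None:
        if not any(
            np.allclose(r, np.eye(3)) and np.allclose(t % 1.0, 0.0)
            for r, t in zip(self.rotations, self.translations)
        ):
            raise ValueError(f"{self.name}: identity operator missing")
        for r1, t1 in zip(self.rotations, self.translations):
            for r2, t2 in zip(self.rotations, self.translations):
                r = r1 @ r2
                t = (r1 @ t2 + t1) % 1.0
                ok = any(
                    np.allclose(r, rr)
                    and np.allclose(np.minimum(d := (t - tt) % 1.0, 1.0 - d), 0.0,
                                    atol=1e-9)
                    for rr, tt in zip(self.rotations, self.translations)
                )
                if not ok:
                    raise ValueError(f"{self.name}: operators not closed")

    def point_group_rotations(self) -> np.ndarray:
        """Unique rotation parts - the point group acting on (h,k,l)."""
        uniq: list[np.ndarray] = []
        for r in np.rint(self.rotations).astype(int):
            if not any(np.array_equal(r, u) for u in uniq):
                uniq.append(r)
        return np.array(uniq)


@dataclass(frozen=True)
class SupercellSpec:
    """Replication counts plus the cell/symmetry they tile."""

    n_a: int
    n_b: int
    n_c: int
    cell: UnitCell
    spacegroup: SpaceGroup | None = None

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.n_c) < 1:
            raise ValueError("replication counts must be >= 1")


# --------------------------------------------------------------------------
# atom containers

@dataclass
class LabeledAtomSet:
    """Array-of-columns container for atoms at any construction stage.

    ``molecule`` partitions atoms into rigid-body groups (one protein copy,
    one water or one ion each); it is renumbered uniquely by the expansion
    and replication steps.
    """

    element: np.ndarray  # chemical symbols
    name: np.ndarray  # atom names
    residue: np.ndarray  # residue labels
    resseq: np.ndarray  # residue sequence numbers
    molecule: np.ndarray  # rigid-group index
    xyz: np.ndarray  # (n, 3) cartesian angstroms
    occupancy: np.ndarray
    b_factor: np.ndarray
    cell: UnitCell | None = None
    spacegroup_name: str | None = None

    def __post_init__(self) -> None:
        n = len(self.xyz)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(n, 3)
        for attr in ("element", "name", "residue", "resseq", "molecule",
                     "occupancy", "b_factor"):
            setattr(self, attr, np.asarray(getattr(self, attr)))
            if len(getattr(self, attr)) != n:
                raise ValueError(f"column {attr} has wrong length")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        if np.any((self.occupancy < 0) | (self.occupancy > 1)):
            raise ValueError("occupancy outside [0, 1]")
        if np.any(self.b_factor < 0):
            raise ValueError("negative B factor")

    def __len__(self) -> int:
        return len(self.xyz)

    def copy(self) -> "LabeledAtomSet":
        return LabeledAtomSet(
            self.element.copy(), self.name.copy(), self.residue.copy(),
            self.resseq.copy(), self.molecule.copy(), self.xyz.copy(),
            self.occupancy.copy(), self.b_factor.copy(),
            self.cell, self.spacegroup_name,
        )

    def with_xyz(self, xyz: np.ndarray) -> "LabeledAtomSet":
        out = self.copy()
        out.xyz = np.asarray(xyz, dtype=float).reshape(len(self), 3)
        if not np.all(np.isfinite(out.xyz)):
            raise ValueError("non-finite coordinates")
        return out

    @classmethod
    def from_arrays(cls, element, xyz, *, name=None, residue=None, resseq=None,
                    molecule=None, occupancy=None, b_factor=None,
                    cell=None, spacegroup_name=None) -> "LabeledAtomSet":
        n = len(xyz)
        return cls(
            np.asarray(element, dtype=object),
            np.asarray(name if name is not None else element, dtype=object),
            np.asarray(residue if residue is not None else ["UNK"] * n, dtype=object),
            np.asarray(resseq if resseq is not None else np.ones(n, dtype=int)),
            np.asarray(molecule if molecule is not None else np.zeros(n, dtype=int)),
            np.asarray(xyz, dtype=float),
            np.asarray(occupancy if occupancy is not None else np.ones(n)),
            np.asarray(b_factor if b_factor is not None else np.zeros(n)),
            cell, spacegroup_name,
        )

    @classmethod
    def concatenate(cls, parts) -> "LabeledAtomSet":
        parts = list(parts)
        return cls(
            *[np.concatenate([getattr(p, f) for p in parts])
              for f in ("element", "name", "residue", "resseq", "molecule")],
            np.vstack([p.xyz for p in parts]),
            np.concatenate([p.occupancy for p in parts]),
            np.concatenate([p.b_factor for p in parts]),
            parts[0].cell, parts[0].spacegroup_name,
        )


@dataclass
class Ensemble:
    """Ordered snapshots sharing one atom roster (stand-in for MD frames)."""

    base: LabeledAtomSet
    coords: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (len(self.base), 3):
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.n_frames < 1:
            raise ValueError("ensemble needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> LabeledAtomSet:
        return self.base.with_xyz(self.coords[i])

    def frames(self):
        return (self.frame(i) for i in range(self.n_frames))

    @classmethod
    def from_snapshots(cls, snapshots) -> "Ensemble":
        snapshots = list(snapshots)
        return cls(snapshots[0], np.stack([s.xyz for s in snapshots]))


# --------------------------------------------------------------------------
# PDB I/O (gemmi-backed)

def _validate_pdb_text(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise ValueError(
                        f"malformed coordinate field {fieldtxt!r} "
                        f"on line {lineno}"
                    ) from None


def _model_to_atomset(model, cell, sg_name) -> LabeledAtomSet:
    cols: dict[str, list] = {k: [] for k in
                             ("element", "name", "residue", "resseq",
                              "molecule", "occ", "b")}
    xyz = []
    mol = -1
    for chain in model:
        chain_mol = None
        for res in chain:
            single = res.is_water() or len(res) == 1
            if single or chain_mol is None:
                mol += 1
                if not single:
                    chain_mol = mol
            use_mol = mol if single else chain_mol
            for at in res:
                if at.element.name in ("X", ""):
                    raise ValueError(
                        f"unknown element for atom {at.name!r} in residue "
                        f"{res.name} {res.seqid.num}"
                    )
                cols["element"].append(at.element.name)
                cols["name"].append(at.name)
                cols["residue"].append(res.name)
                cols["resseq"].append(res.seqid.num)
                cols["molecule"].append(use_mol)
                cols["occ"].append(at.occ)
                cols["b"].append(at.b_iso)
                xyz.append([at.pos.x, at.pos.y, at.pos.z])
    if not xyz:
        raise ValueError("no ATOM/HETATM records found")
    return LabeledAtomSet(
        np.array(cols["element"], dtype=object),
        np.array(cols["name"], dtype=object),
        np.array(cols["residue"], dtype=object),
        np.array(cols["resseq"], dtype=int),
        np.array(cols["molecule"], dtype=int),
        np.array(xyz),
        np.array(cols["occ"], dtype=float),
        np.array(cols["b"], dtype=float),
        cell, sg_name,
    )


def read_structure(pdb_text: str):
    """Parse PDB text into a LabeledAtomSet, or an Ensemble for multi-model.

    CRYST1 is honored when present (cell + space-group symbol).  Elements
    come from the element column with atom-name inference as fallback.
    """
    _validate_pdb_text(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    cell = None
    if st.cell and st.cell.a > 1.0:
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg_name = st.spacegroup_hm or None
    sets = [_model_to_atomset(m, cell, sg_name) for m in st]
    if len(sets) == 1:
        return sets[0]
    return Ensemble.from_snapshots(sets)


def write_structure(atoms: LabeledAtomSet | Ensemble, path=None) -> str:
    """Render as PDB text (CRYST1 carries the cell when known); optionally save."""
    frames = [atoms] if isinstance(atoms, LabeledAtomSet) else list(atoms.frames())
    base = frames[0]
    lines = []
    if base.cell is not None:
        c = base.cell
        sg = base.spacegroup_name or "P 1"
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} {sg:<11s}"
        )
    multi = len(frames) > 1
    for imodel, fr in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {imodel:4d}")
        for i in range(len(fr)):
            serial = (i + 1) % 100000
            name = str(fr.name[i])
            pad = name if len(name) >= 4 else f" {name:<3s}"
            rec = "HETATM" if str(fr.residue[i]) in ("HOH", "WAT") or len(
                str(fr.element[i])) == len(name.strip()) == 2 else "ATOM  "
            x, y, z = fr.xyz[i]
            lines.append(
                f"{rec}{serial:5d} {pad:<4s} {str(fr.residue[i])[:3]:<3s} A"
                f"{int(fr.resseq[i]) % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{fr.occupancy[i]:6.2f}"
                f"{fr.b_factor[i]:6.2f}          {str(fr.element[i]):>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# --------------------------------------------------------------------------
# symmetry expansion and replication

def expand_asymmetric_unit(asu: LabeledAtomSet, sg: SpaceGroup,
                           cell: UnitCell) -> LabeledAtomSet:
    """Apply every space-group operator to the ASU; one unit cell out.

    Each copy is fractionalize -> operator -> orthogonalize; molecule
    indices are renumbered uniquely so each symmetry copy stays one rigid
    group per input molecule.
    """
    frac = asu.xyz @ cell.fractionalization.T
    n_mol = int(asu.molecule.max()) + 1 if len(asu) else 0
    copies = []
    for i, (rot, tran) in enumerate(zip(sg.rotations, sg.translations)):
        new_frac = frac @ rot.T + tran
        copy = asu.with_xyz(new_frac @ cell.orthogonalization.T)
        copy.molecule = asu.molecule + i * n_mol
        copies.append(copy)
    out = LabeledAtomSet.concatenate(copies)
    out.cell = cell
    out.spacegroup_name = sg.name
    return out


def build_supercell(cell_contents: LabeledAtomSet,
                    spec: SupercellSpec) -> LabeledAtomSet:
    """Tile one full unit cell onto the n_a x n_b x n_c translation lattice."""
    m = spec.cell.orthogonalization
    n_mol = int(cell_contents.molecule.max()) + 1
    blocks = []
    i = 0
    for ia in range(spec.n_a):
        for ib in range(spec.n_b):
            for ic in range(spec.n_c):
                shift = m @ np.array([ia, ib, ic], dtype=float)
                blk = cell_contents.with_xyz(cell_contents.xyz + shift)
                blk.molecule = cell_contents.molecule + i * n_mol
                blocks.append(blk)
                i += 1
    out = LabeledAtomSet.concatenate(blocks)
    out.cell = spec.cell
    out.spacegroup_name = (spec.spacegroup.name if spec.spacegroup
                           else cell_contents.spacegroup_name)
    return out


# --------------------------------------------------------------------------
# solvent and ions

_WATER_GEOMETRY = None


def _water_sites() -> np.ndarray:
    """Rigid 3-site water: O at origin, O-H 1.0 A, H-O-H 109.47 deg."""
    global _WATER_GEOMETRY
    if _WATER_GEOMETRY is None:
        half = math.radians(109.47 / 2)
        _WATER_GEOMETRY = np.array(
            [[0.0, 0.0, 0.0],
             [math.sin(half), 0.0, math.cos(half)],
             [-math.sin(half), 0.0, math.cos(half)]]
        )
    return _WATER_GEOMETRY


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # quaternion draw: uniform over SO(3)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _place_random(host_heavy: np.ndarray, box: np.ndarray, n: int,
                  min_dist: float, rng: np.random.Generator,
                  max_attempts: int):
    """Rejection-sample n positions >= min_dist from host heavy atoms and
    from each other.  Returns the accepted positions."""
    tree = cKDTree(host_heavy) if len(host_heavy) else None
    placed: list[np.ndarray] = []
    placed_tree = None
    attempts = 0
    while len(placed) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"placement failed: {len(placed)} of {n} placed "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        pos = rng.random(3) * box
        if tree is not None and tree.query(pos, k=1)[0] < min_dist:
            continue
        if placed:
            if placed_tree is None or len(placed) % 64 == 0:
                placed_tree = cKDTree(np.array(placed))
            d, _ = placed_tree.query(pos, k=1)
            if d < min_dist:
                continue
            recent = np.array(placed[(len(placed) // 64) * 64:])
            if len(recent) and np.min(
                    np.linalg.norm(recent - pos, axis=1)) < min_dist:
                continue
        placed.append(pos)
    return np.array(placed).reshape(len(placed), 3)


def solvate_random(host: LabeledAtomSet, box, n_waters: int, min_dist: float,
                   seed: int, max_attempts_per_water: int = 2000) -> LabeledAtomSet:
    """Add rigid 3-site waters at uniformly random positions/orientations.

    Every new oxygen keeps >= min_dist from all existing heavy (non-H)
    atoms and previously placed oxygens.  Deterministic given seed.
    """
    if n_waters < 0:
        raise ValueError("n_waters must be >= 0")
    if min_dist <= 0:
        raise ValueError("min_dist must be > 0")
    if n_waters == 0:
        return host.copy()
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    heavy = host.xyz[host.element != "H"]
    centers = _place_random(heavy, box, n_waters, min_dist, rng,
                            max_attempts_per_water * n_waters)
    sites = _water_sites()
    xyz = np.empty((n_waters * 3, 3))
    for i, c in enumerate(centers):
        xyz[3 * i: 3 * i + 3] = c + sites @ _random_rotation(rng).T
    mol0 = int(host.molecule.max()) + 1 if len(host) else 0
    res0 = int(host.resseq.max()) + 1 if len(host) else 1
    waters = LabeledAtomSet.from_arrays(
        element=np.array(["O", "H", "H"] * n_waters, dtype=object),
        xyz=xyz,
        name=np.array(["O", "H1", "H2"] * n_waters, dtype=object),
        residue=np.array(["HOH"] * (3 * n_waters), dtype=object),
        resseq=np.repeat(np.arange(res0, res0 + n_waters), 3),
        molecule=np.repeat(np.arange(mol0, mol0 + n_waters), 3),
        cell=host.cell, spacegroup_name=host.spacegroup_name,
    )
    return LabeledAtomSet.concatenate([host, waters])


#: Formal charges per residue label.  The protonation variants (ASH/GLH =
#: protonated Asp/Glu) are neutral entries; HIS is neutral by default.
DEFAULT_CHARGE_SCHEME: dict[str, int] = {
    "ARG": 1, "LYS": 1, "ASP": -1, "GLU": -1, "HIS": 0, "ASH": 0, "GLH": 0,
    "CYX": 0, "HOH": 0, "WAT": 0, "CL": -1, "NA": 1,
}

_ION_CHARGE = {"Cl": -1, "Br": -1, "I": -1, "F": -1, "Na": 1, "K": 1}


def formal_charge(host: LabeledAtomSet, charge_scheme=None) -> int:
    """Net formal charge from the per-residue scheme (one count per residue)."""
    scheme = dict(DEFAULT_CHARGE_SCHEME)
    if charge_scheme:
        scheme.update({k.upper(): v for k, v in charge_scheme.items()})
    seen = set()
    total = 0
    missing = set()
    for res, seq, mol in zip(host.residue, host.resseq, host.molecule):
        key = (str(res), int(seq), int(mol))
        if key in seen:
            continue
        seen.add(key)
        label = str(res).upper()
        if label not in scheme:
            missing.add(label)
        else:
            total += scheme[label]
    if missing:
        raise ValueError(
            "charge scheme missing residues: " + ", ".join(sorted(missing))
        )
    return total


def neutralize(host: LabeledAtomSet, charge_scheme=None, ion_element: str = "Cl",
               seed: int = 0, min_dist: float = 2.4, box=None,
               max_attempts_per_ion: int = 2000) -> LabeledAtomSet:
    """Add ceil(|net charge|) monatomic counter-ions at random clash-free spots.

    The ion element is taken at face value (e.g. 'Cl' to neutralize a net
    positive charge, 'Na' for a net negative one); the signed ion charge
    must oppose the host's net charge.
    """
    net = formal_charge(host, charge_scheme)
    n_ions = math.ceil(abs(net))
    if n_ions == 0:
        return host.copy()
    ion_charge = _ION_CHARGE.get(ion_element.capitalize())
    if ion_charge is None:
        raise ValueError(f"no formal charge known for ion element {ion_element!r}")
    if np.sign(ion_charge) == np.sign(net):
        raise ValueError(
            f"{ion_element} ions (charge {ion_charge:+d}) cannot neutralize "
            f"net charge {net:+d}"
        )
    if box is None:
        if host.cell is not None:
            box = np.diag(host.cell.orthogonalization)
        else:
            box = host.xyz.max(axis=0) - host.xyz.min(axis=0) + 4.0
    rng = np.random.default_rng(seed)
    heavy = host.xyz[host.element != "H"]
    pos = _place_random(heavy, np.asarray(box, dtype=float), n_ions, min_dist,
                        rng, max_attempts_per_ion * n_ions)
    mol0 = int(host.molecule.max()) + 1
    res0 = int(host.resseq.max()) + 1
    label = ion_element.upper()
    ions = LabeledAtomSet.from_arrays(
        element=np.array([ion_element.capitalize()] * n_ions, dtype=object),
        xyz=pos,
        name=np.array([label] * n_ions, dtype=object),
        residue=np.array([label] * n_ions, dtype=object),
        resseq=np.arange(res0, res0 + n_ions),
        molecule=np.arange(mol0, mol0 + n_ions),
        cell=host.cell, spacegroup_name=host.spacegroup_name,
    )
    return LabeledAtomSet.concatenate([host, ions])
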