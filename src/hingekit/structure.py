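"""Backbone structure container, PDB I/O, helix detection and rigid-body geometry.

The package works on backbone-only models: every residue carries N, CA, C
(O optional at a chain C-terminus, CB optional everywhere).  Coordinates are
in angstroms, residue indices are 1-based and strictly increasing within a
chain.  Helices are detected from CA geometry alone so that the machinery is
independent of sequence and of hydrogen-bond assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")

#: CA(i)->CA(i+3) distance window (A) for alpha-helical geometry.
HELIX_D13 = (4.5, 5.7)
#: four-CA virtual torsion window (degrees) for alpha-helical geometry.
HELIX_TORSION = (40.0, 60.0)
#: CA-CA virtual bond sanity window (A); larger gaps are chain breaks.
CA_CA_RANGE = (2.8, 4.2)


class StructureError(ValueError):
    """Raised for malformed or underdetermined structural input."""


@dataclass
class Residue:
    chain_id: str
    res_index: int
    coords: dict[str, np.ndarray]

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.res_index,
                       {k: v.copy() for k, v in self.coords.items()})


@dataclass
class BackboneStructure:
    """Ordered list of backbone residues with optional per-residue segment tags."""

    residues: list[Residue]
    segment_labels: list[str] | None = None

    def __len__(self) -> int:
        return len(self.residues)

    def copy(self) -> "BackboneStructure":
        labels = list(self.segment_labels) if self.segment_labels else None
        return BackboneStructure([r.copy() for r in self.residues], labels)

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def chain(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def coords_of(self, atom: str = "CA") -> np.ndarray:
        """(n, 3) array of one atom type across all residues (must be present)."""
        rows = []
        for r in self.residues:
            if atom not in r.coords:
                raise StructureError(
                    f"atom {atom} missing in chain {r.chain_id} residue {r.res_index}")
            rows.append(r.coords[atom])
        return np.asarray(rows, dtype=float)

    def all_atoms(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten to (coords, residue number, chain ordinal) arrays.

        Residue numbers carry sequence separation (used for bonded-pair
        exclusion); they are only comparable within one chain.
        """
        chain_ord = {c: i for i, c in enumerate(self.chain_ids())}
        xyz, rid, cid = [], [], []
        for r in self.residues:
            for name in BACKBONE_ATOMS:
                if name in r.coords:
                    xyz.append(r.coords[name])
                    rid.append(r.res_index)
                    cid.append(chain_ord[r.chain_id])
        return np.asarray(xyz, float), np.asarray(rid), np.asarray(cid)

    def transformed(self, transform: "RigidTransform") -> "BackboneStructure":
        out = self.copy()
        for r in out.residues:
            for k in r.coords:
                r.coords[k] = transform.apply(r.coords[k])
        return out

    def validate(self) -> None:
        for r in self.residues:
            for name in ("N", "CA", "C"):
                if name not in r.coords:
                    raise StructureError(
                        f"missing backbone atom {name} in chain {r.chain_id} "
                        f"residue {r.res_index}")
        for cid in self.chain_ids():
            chain = self.chain(cid)
            idx = [r.res_index for r in chain]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise StructureError(f"res_index not strictly increasing in chain {cid}")


@dataclass
class HelixSegment:
    """A helical run of residues with a fitted cylinder axis.

    ``start``/``end`` are 1-based inclusive positions in the residue list of
    ``chain_id``.  ``rise`` is A/residue along ``axis_dir``; ``twist`` is
    degrees/residue about it.
    """

    chain_id: str
    start: int
    end: int
    axis_point: np.ndarray | None = None
    axis_dir: np.ndarray | None = None
    rise: float | None = None
    twist: float | None = None
    residual: float | None = None
    flagged: bool = False

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float = 0.0
    warning: bool = False

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self @ other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi; ATOM records only)

def read_backbone(path) -> BackboneStructure:
    """Read a backbone-only structure from PDB.

    Waters and hetero records are skipped; altlocs are resolved to the highest
    occupancy (ties by altloc identifier order).  A missing N/CA/C atom is a
    hard error naming the offending residue.  Chain breaks are tolerated (they
    become segment boundaries downstream).
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise StructureError(f"no model in {path}")
    model = st[0]
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.is_water() or res.het_flag == "H":
                continue
            coords: dict[str, np.ndarray] = {}
            for name in BACKBONE_ATOMS:
                best = None
                for atom in res:
                    if atom.name != name:
                        continue
                    key = (atom.occ, -ord(atom.altloc or "\x7f"))
                    if best is None or key > best[0]:
                        best = (key, atom)
                if best is not None:
                    a = best[1]
                    coords[name] = np.array([a.pos.x, a.pos.y, a.pos.z])
            missing = [n for n in ("N", "CA", "C") if n not in coords]
            if missing:
                raise StructureError(
                    f"missing backbone atom(s) {'/'.join(missing)} in chain "
                    f"{chain.name} residue {res.seqid.num}")
            residues.append(Residue(chain.name, res.seqid.num, coords))
    out = BackboneStructure(residues)
    out.validate()
    return out


def write_backbone(structure: BackboneStructure, path) -> None:
    """Write ATOM records (occupancy 1.00, B 0.00); GLY without CB, ALA with."""
    st = gemmi.Structure()
    st.name = "hingekit"
    model = gemmi.Model("1")
    for cid in structure.chain_ids():
        chain = gemmi.Chain(cid)
        for r in structure.chain(cid):
            res = gemmi.Residue()
            res.name = "ALA" if "CB" in r.coords else "GLY"
            res.seqid = gemmi.SeqId(r.res_index, " ")
            for name in BACKBONE_ATOMS:
                if name not in r.coords:
                    continue
                atom = gemmi.Atom()
                atom.name = name
                x, y, z = (float(v) for v in r.coords[name])
                atom.pos = gemmi.Position(x, y, z)
                atom.occ = 1.0
                atom.b_iso = 0.0
                atom.element = gemmi.Element(name[0])
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Ideal CB construction

CB_LENGTH = 1.521  # A, CA-CB bond


def build_cb(structure: BackboneStructure) -> BackboneStructure:
    """Add an ideal CB to every residue lacking one.

    The CB direction is built from the local N, CA, C frame with standard
    tetrahedral geometry and L-chirality; the bond length is exactly
    ``CB_LENGTH``.  Existing CBs are left untouched.  All contact, staple and
    label-site distances in the package use these CBs, which keeps results
    sequence-independent.
    """
    out = structure.copy()
    for r in out.residues:
        if "CB" in r.coords:
            continue
        n, ca, c = r.coords["N"], r.coords["CA"], r.coords["C"]
        b = ca - n
        cvec = c - ca
        a = np.cross(b, cvec)
        # classic ideal-geometry linear combination, rescaled to the exact bond
        direction = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cvec
        direction /= np.linalg.norm(direction)
        r.coords["CB"] = ca + CB_LENGTH * direction
    return out


# ---------------------------------------------------------------------------
# Helix detection

def _torsion(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def detect_helices(structure: BackboneStructure, min_len: int = 6) -> list[HelixSegment]:
    """Report maximal alpha-helical runs per chain from CA-only criteria.

    Residue window i..i+3 qualifies when d(CA_i, CA_{i+3}) lies in
    ``HELIX_D13`` and the four-CA virtual torsion lies in ``HELIX_TORSION``.
    Maximal runs of qualifying windows span residues i..i+3 of the last
    window; runs shorter than ``min_len`` residues are dropped.  Chain breaks
    (CA-CA > 4.2 A) terminate runs.  Returned segments never overlap.
    """
    segments: list[HelixSegment] = []
    for cid in structure.chain_ids():
        chain = structure.chain(cid)
        ca = np.array([r.coords["CA"] for r in chain])
        n = len(chain)
        if n < 4:
            continue
        ok = np.zeros(n - 3, bool)
        for i in range(n - 3):
            steps = np.linalg.norm(np.diff(ca[i:i + 4], axis=0), axis=1)
            if steps.max() > CA_CA_RANGE[1]:
                continue  # chain break inside window
            d13 = np.linalg.norm(ca[i + 3] - ca[i])
            if not (HELIX_D13[0] <= d13 <= HELIX_D13[1]):
                continue
            tors = _torsion(*ca[i:i + 4])
            if HELIX_TORSION[0] <= tors <= HELIX_TORSION[1]:
                ok[i] = True
        i = 0
        prev_end = 0  # 1-based end of previous emitted segment
        while i < len(ok):
            if not ok[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(ok) and ok[j + 1]:
                j += 1
            start, end = i + 1, j + 4  # 1-based inclusive
            start = max(start, prev_end + 1)
            if end - start + 1 >= min_len:
                segments.append(HelixSegment(cid, start, end))
                prev_end = end
            i = j + 1
    return segments


# ---------------------------------------------------------------------------
# Superposition and helix-axis fitting

def superpose(mobile_coords: np.ndarray, target_coords: np.ndarray
              ) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch, proper rotation only).

    Returns the transform mapping ``mobile_coords`` onto ``target_coords``
    and the post-fit RMSD.  Requires >= 3 non-collinear points.
    """
    P = np.asarray(mobile_coords, float)
    Q = np.asarray(target_coords, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise StructureError("point sets must be equal-shaped (n, 3)")
    if len(P) < 3:
        raise StructureError("need at least 3 points to superpose")
    pc, qc = P.mean(0), Q.mean(0)
    P0, Q0 = P - pc, Q - qc
    s = np.linalg.svd(P0, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise StructureError("points are collinear; rotation underdetermined")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return RigidTransform(R, t, rmsd=rmsd), rmsd


def fit_helix_axis(structure: BackboneStructure, segment: HelixSegment
                   ) -> HelixSegment:
    """Fit the helix axis, rise and twist of a residue range.

    The per-residue screw operator is estimated by superposing CA[0:n-1] onto
    CA[1:n]; its Chasles decomposition gives the axis direction, the twist
    (rotation/residue) and the rise (translation/residue).  This is exact for
    an ideal helix and a total-least-squares compromise otherwise.  The axis
    is oriented from N- to C-terminus so the rise is positive.  A fit residual
    above 1.0 A RMS flags the segment as non-helical (axis still returned).
    """
    from .geometry import screw_decompose  # local import to avoid a cycle

    chain = structure.chain(segment.chain_id)
    if segment.start < 1 or segment.end > len(chain):
        raise StructureError("segment out of range")
    ca = np.array([r.coords["CA"] for r in chain[segment.start - 1:segment.end]])
    if len(ca) < 6:
        raise StructureError("segment too short to fit an axis (need >= 6)")
    t, rmsd = superpose(ca[:-1], ca[1:])
    axis_point, axis_dir, angle, slide, degenerate = screw_decompose(t)
    if degenerate:
        # straight translation; direction of travel is the axis
        axis_dir = (ca[-1] - ca[0]) / np.linalg.norm(ca[-1] - ca[0])
        axis_point = ca.mean(0)
        angle = 0.0
        slide = float(np.dot(ca[-1] - ca[0], axis_dir)) / (len(ca) - 1)
    if np.dot(axis_dir, ca[-1] - ca[0]) < 0:
        axis_dir = -axis_dir
        slide = -slide
        angle = -angle
    twist = angle % 360.0
    if twist > 180.0:
        twist -= 360.0
    centroid = ca.mean(0)
    axis_point = axis_point + np.dot(centroid - axis_point, axis_dir) * axis_dir
    return replace(segment, axis_point=axis_point, axis_dir=axis_dir,
                   rise=float(slide), twist=float(twist), residual=rmsd,
                   flagged=rmsd > 1.0)
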