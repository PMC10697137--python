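"""Deterministic synthetic helical-repeat scaffolds.

Stand-ins for designed helical repeat proteins (DHRs): regular arrays of
straight, ideal alpha-helices (two per repeat, antiparallel up-down), short
geometric loops, no steric clashes.  Helix axes are exactly straight and
every helix is exactly screw-symmetric, so screw-recovery and axis-fitting
oracles are analytic.  Loops are CA-path placeholders bulged into circular
arcs to keep virtual-bond lengths sane; nothing in the package scores loop
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .structure import BackboneStructure, HelixSegment, Residue, RigidTransform
from .geometry import clash_count

# Local-frame offsets (radial, tangential, axial; A) of N, C, O relative to
# CA for a helically symmetric backbone with CA radius 2.3 A.  Solved once
# against standard bond lengths/angles at rise 1.5 A, twist 100 deg/res,
# with O(i)..N(i+4) held above the 3.2 A clash cutoff.
CA_RADIUS = 2.3
_OFFSETS = {
    "N": np.array([-0.914945, -0.709277, -0.903149]),
    "C": np.array([-0.773491, 0.818888, 1.042724]),
    "O": np.array([-0.109173, 1.299193, 1.960831]),
}


def ideal_helix(n: int, rise: float = 1.5, twist: float = 100.0,
                chain_id: str = "A", phase: float = 0.0,
                start_index: int = 1) -> BackboneStructure:
    """Ideal alpha-helix of ``n`` residues along +z.

    Backbone atoms are placed in a per-residue frame that co-rotates with the
    CA helix (radius ~2.3 A), so the structure is exactly screw-symmetric
    with the given rise (A/residue) and twist (degrees/residue).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    residues = []
    for i in range(n):
        th = np.radians(phase + i * twist)
        ca = np.array([CA_RADIUS * np.cos(th), CA_RADIUS * np.sin(th), i * rise])
        e_r = np.array([np.cos(th), np.sin(th), 0.0])
        e_t = np.array([-np.sin(th), np.cos(th), 0.0])
        e_z = np.array([0.0, 0.0, 1.0])
        coords = {"CA": ca}
        for name, (a, b, c) in _OFFSETS.items():
            coords[name] = ca + a * e_r + b * e_t + c * e_z
        residues.append(Residue(chain_id, start_index + i, coords))
    return BackboneStructure(residues)


@dataclass
class RepeatSpec:
    """Parameters of the synthetic helical repeat scaffold.

    ``pack_dist`` is the distance between adjacent helix axes in the
    two-layer hexagonal packing; ``repeat_twist`` curves the repeat array by
    rotating each repeat about z relative to the previous one.
    """

    n_repeats: int = 4
    helices_per_repeat: int = 2
    helix_len: int = 20
    loop_len: int = 3
    helix_rise: float = 1.5
    helix_twist: float = 100.0
    pack_dist: float = 10.0
    repeat_twist: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ValueError("need n_repeats >= 2")
        if self.helices_per_repeat != 2:
            raise ValueError("only 2 helices per repeat supported")
        if min(self.helix_len, self.loop_len) < 0 or self.helix_len < 8:
            raise ValueError("helix_len must be >= 8 and loop_len >= 0")
        for name in ("helix_rise", "helix_twist", "pack_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _arc_path(p0: np.ndarray, p1: np.ndarray, n_interior: int,
              bulge_dir: np.ndarray, target_step: float = 3.5) -> np.ndarray:
    """Interior points of a circular arc from p0 to p1 with ~equal chord steps.

    The arc bulges toward ``bulge_dir`` until each of the ``n_interior + 1``
    steps is close to ``target_step`` (never below the straight-line step).
    """
    n_steps = n_interior + 1
    chord = float(np.linalg.norm(p1 - p0))
    if n_interior == 0:
        return np.empty((0, 3))
    straight_step = chord / n_steps
    if straight_step >= target_step - 1e-9:
        ts = np.linspace(0.0, 1.0, n_steps + 1)[1:-1]
        return p0 + np.outer(ts, p1 - p0)
    arc_len = target_step * n_steps
    # solve sin(a)/a = chord/arc_len for the half-angle a by bisection
    ratio = chord / arc_len
    lo, hi = 1e-9, np.pi - 1e-9
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.sin(mid) / mid > ratio:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    R = chord / (2.0 * np.sin(a))
    u = (p1 - p0) / chord
    v = bulge_dir - np.dot(bulge_dir, u) * u
    v = v / np.linalg.norm(v)
    center = 0.5 * (p0 + p1) - v * R * np.cos(a)
    phis = np.linspace(-a, a, n_steps + 1)[1:-1]
    return np.array([center + R * (np.sin(phi) * u + np.cos(phi) * v)
                     for phi in phis])


def _loop_residues(path: np.ndarray, before: np.ndarray, after: np.ndarray,
                   chain_id: str, start_index: int) -> list[Residue]:
    """Place N/CA/C/O along a CA path (geometric placeholders)."""
    residues = []
    for k, ca in enumerate(path):
        prev_pt = path[k - 1] if k > 0 else before
        next_pt = path[k + 1] if k + 1 < len(path) else after
        u_in = (ca - prev_pt) / np.linalg.norm(ca - prev_pt)
        u_out = (next_pt - ca) / np.linalg.norm(next_pt - ca)
        perp = np.cross(u_in, u_out)
        if np.linalg.norm(perp) < 1e-6:
            ref = np.array([0.0, 0.0, 1.0])
            if abs(np.dot(u_out, ref)) > 0.9:
                ref = np.array([1.0, 0.0, 0.0])
            perp = np.cross(u_out, ref)
        perp = perp / np.linalg.norm(perp)
        coords = {
            "CA": ca,
            "N": ca - 1.25 * u_in,
            "C": ca + 1.25 * u_out,
        }
        coords["O"] = coords["C"] + 1.23 * perp
        residues.append(Residue(chain_id, start_index + k, coords))
    return residues


def repeat_operator(spec: RepeatSpec) -> RigidTransform:
    """Rigid operator mapping repeat k onto repeat k+1."""
    return RigidTransform(_rot_z(spec.repeat_twist),
                          np.array([spec.pack_dist, 0.0, 0.0]))


def build_repeat_protein(spec: RepeatSpec
                         ) -> tuple[BackboneStructure, dict]:
    """Build the scaffold; returns (structure, metadata).

    Helices alternate up/down in two layers offset by half a repeat spacing
    (hexagonal packing, adjacent axes ``pack_dist`` apart); consecutive
    repeats are related by :func:`repeat_operator`.  Metadata records the
    true helix boundaries (1-based, inclusive) and the spec.  Raises if the
    parameters produce steric clashes.
    """
    n_h = 2 * spec.n_repeats
    height = (spec.helix_len - 1) * spec.helix_rise
    layer_dy = spec.pack_dist * np.sqrt(3.0) / 2.0
    op = repeat_operator(spec)

    # repeat-0 helix placements: (origin translation, flip, phase)
    placements = []
    for j in range(n_h):
        k, slot = divmod(j, 2)
        base = np.array([slot * spec.pack_dist / 2.0, slot * layer_dy, 0.0])
        t = RigidTransform(np.eye(3), base)
        for _ in range(k):
            t = op.compose(t)
        placements.append((t, slot == 1))

    residues: list[Residue] = []
    labels: list[str] = []
    helix_ranges: list[tuple[int, int]] = []
    prev_end_ca = None
    for j, (t, flip) in enumerate(placements):
        # fixed azimuthal phase: keeps repeats congruent and maximises the
        # inter-helix steric margin across helix lengths
        helix = ideal_helix(spec.helix_len, spec.helix_rise, spec.helix_twist,
                            phase=80.0)
        coords_list = []
        for r in helix.residues:
            cc = {}
            for name, v in r.coords.items():
                p = v.copy()
                if flip:  # down helix: rotate 180 deg about x, shift back up
                    p = np.array([p[0], -p[1], -p[2]]) + np.array([0, 0, height])
                cc[name] = t.apply(p)
            coords_list.append(cc)
        start_ca = coords_list[0]["CA"]
        if prev_end_ca is not None:
            # odd j: previous (up) helix ends at the top -> loop bulges up
            top_loop = (j % 2 == 1)
            bulge = np.array([0.0, 0.0, 1.0 if top_loop else -1.0])
            path = _arc_path(prev_end_ca, start_ca, spec.loop_len, bulge)
            loop = _loop_residues(path, prev_end_ca, start_ca, "A",
                                  len(residues) + 1)
            residues.extend(loop)
            labels.extend(["loop"] * len(loop))
        h_start = len(residues) + 1
        for cc in coords_list:
            residues.append(Residue("A", len(residues) + 1, cc))
            labels.append(f"H{j}")
        helix_ranges.append((h_start, len(residues)))
        prev_end_ca = coords_list[-1]["CA"]

    structure = BackboneStructure(residues, labels)
    structure.validate()
    n_clash = clash_count(structure)
    if n_clash > 0:
        raise ValueError(f"spec produces {n_clash} steric clash(es); "
                         "increase pack_dist or shorten helices")
    meta = {
        "helix_ranges": helix_ranges,
        "n_helices": n_h,
        "spec": asdict(spec),
    }
    return structure, meta


def helix_segments_from_meta(meta: dict) -> list[HelixSegment]:
    """True helix boundaries from generator metadata as HelixSegment list."""
    return [HelixSegment("A", s, e) for s, e in meta["helix_ranges"]]
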