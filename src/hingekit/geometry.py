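"""Pivot-helix register-shift geometry and two-state model assembly.

The second conformation (state Y) of a hinge is generated by sliding the
alignment of a copy of the parent protein along a "pivot" helix by an integer
register shift.  Because an ideal helix is screw-symmetric, a shift of ``s``
residues induces a screw motion of approximately ``s x twist`` degrees about
the pivot axis and ``s x rise`` angstroms along it.  State Y is assembled
from domain 1 (helices 1..p of the parent, untouched) and domain 2 (helices
p+1..n of the moved copy); the helix vacated next to the pivot becomes the
effector peptide.  Designs are gated by a surrogate contact energy that
reproduces the two-state selection logic: state X must be lower in energy
than the peptide-free state Y, and the state-Y/peptide complex must be lower
than state X plus the separated peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import (
    BackboneStructure,
    HelixSegment,
    Residue,
    RigidTransform,
    StructureError,
    build_cb,
    detect_helices,
    superpose,
)

#: Maximum CA-CA span of one loop residue step (trans peptide virtual bond).
LOOP_STEP = 3.8


# ---------------------------------------------------------------------------
# Screw (Chasles) decomposition

def screw_decompose(t: RigidTransform
                    ) -> tuple[np.ndarray, np.ndarray, float, float, bool]:
    """Decompose a proper rigid motion into rotation about / slide along one axis.

    Returns ``(axis_point, axis_dir, angle_deg, slide, degenerate)``.  The
    axis is oriented so the slide is non-negative, which places the angle in
    [0, 360).  For near-identity rotations (< 0.1 degrees) the axis is
    undefined: the translation magnitude is reported as the slide and
    ``degenerate`` is True.
    """
    R = t.rotation
    trans = t.translation
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = float(np.degrees(np.arccos(cos_theta)))
    if theta < 0.1:
        norm = np.linalg.norm(trans)
        axis = trans / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
        return np.zeros(3), axis, theta, float(norm), True
    if theta < 179.9:
        w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        axis = w / (2.0 * np.sin(np.radians(theta)))
    else:
        # sin(theta) ~ 0: axis from the dominant column of R + I
        B = R + np.eye(3)
        axis = B[:, np.argmax(np.linalg.norm(B, axis=0))]
    axis = axis / np.linalg.norm(axis)
    slide = float(np.dot(trans, axis))
    if slide < 0:
        axis, slide, theta = -axis, -slide, 360.0 - theta
    # point on the axis: (I - R) a = t_perp, rank-2 system
    t_perp = trans - slide * axis
    a, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    a = a - np.dot(a, axis) * axis  # canonical point: zero axial component
    return a, axis, theta, slide, False


# ---------------------------------------------------------------------------
# Pivot-shift transform

def pivot_shift_transform(parent: BackboneStructure, pivot: HelixSegment,
                          shift_s: int) -> RigidTransform:
    """Transform moving a copy of the parent by a ``shift_s``-residue register
    shift along the pivot helix.

    The CA window of the pivot shortened by ``|shift_s|`` residues is
    superposed onto the window shifted by ``shift_s``; positive shifts move
    the copy toward the C-terminal end of the pivot axis.  A superposition
    RMSD above 0.7 A sets the ``warning`` flag (pivot not regular enough).
    """
    shift_s = int(shift_s)
    chain = parent.chain(pivot.chain_id)
    ca = np.array([r.coords["CA"] for r in chain[pivot.start - 1:pivot.end]])
    L = len(ca)
    if shift_s == 0:
        return RigidTransform.identity()
    if L - abs(shift_s) < 8:
        raise StructureError(
            f"pivot helix of {L} residues leaves < 8 residues of overlap "
            f"for shift {shift_s}")
    s = shift_s
    if s > 0:
        mobile, target = ca[:L - s], ca[s:]
    else:
        mobile, target = ca[-s:], ca[:L + s]
    t, rmsd = superpose(mobile, target)
    t.warning = rmsd > 0.7
    return t


# ---------------------------------------------------------------------------
# Clash counting and surrogate contact energy

def clash_count(model: BackboneStructure, cutoff: float = 3.2,
                bonded_exclusion: int = 2) -> int:
    """Count heavy-atom pairs (N, CA, C, O, CB) closer than ``cutoff``.

    Pairs within the same chain separated by ``bonded_exclusion`` residues or
    fewer are ignored (covalent neighbourhood); pairs across chains always
    count.  Implemented with a k-d tree; identical to the all-pairs answer.
    """
    if len(model) == 0:
        return 0
    xyz, rid, cid = model.all_atoms()
    if len(xyz) == 0:
        return 0
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    i, j = pairs[:, 0], pairs[:, 1]
    same_chain = cid[i] == cid[j]
    sep = np.abs(rid[i] - rid[j])
    return int(np.sum(~same_chain | (sep > bonded_exclusion)))


def clash_count_bruteforce(model: BackboneStructure, cutoff: float = 3.2,
                           bonded_exclusion: int = 2) -> int:
    """All-pairs reference implementation of :func:`clash_count`."""
    xyz, rid, cid = model.all_atoms()
    n = len(xyz)
    count = 0
    for a in range(n):
        for b in range(a + 1, n):
            if cid[a] == cid[b] and abs(rid[a] - rid[b]) <= bonded_exclusion:
                continue
            if np.linalg.norm(xyz[a] - xyz[b]) < cutoff:
                count += 1
    return count


def contact_energy(model: BackboneStructure, partition: np.ndarray,
                   r_contact: float = 8.0, clash_weight: float = 25.0) -> float:
    """Surrogate packing energy: minus the inter-segment CB-CB contact count
    plus a clash penalty.

    ``partition`` assigns each residue to one rigid segment (helix or
    peptide); only contacts between different segments score, so rigid-body
    internal contacts cancel when comparing states.  This reproduces the
    ordering used for two-state selection, not any physical energy scale.
    """
    if len(model) == 0:
        return 0.0
    partition = np.asarray(partition)
    if len(partition) != len(model):
        raise StructureError("partition length must match residue count")
    cb, seg = [], []
    for r, s in zip(model.residues, partition):
        if "CB" in r.coords:
            cb.append(r.coords["CB"])
            seg.append(s)
    contacts = 0
    if cb:
        cb = np.asarray(cb)
        seg = np.asarray(seg)
        tree = cKDTree(cb)
        pairs = tree.query_pairs(r_contact, output_type="ndarray")
        if len(pairs):
            contacts = int(np.sum(seg[pairs[:, 0]] != seg[pairs[:, 1]]))
    return -float(contacts) + clash_weight * clash_count(model)


# ---------------------------------------------------------------------------
# Hinge state assembly

@dataclass
class HingeSpec:
    """Which helix pivots, how far the register shifts, and the peptide rule."""

    pivot_index: int                      # 1-based among detected helices
    shift_s: int
    peptide_rule: str = "following_original"  # or "preceding_copy"

    def __post_init__(self) -> None:
        if self.peptide_rule not in ("following_original", "preceding_copy"):
            raise ValueError(f"unknown peptide_rule {self.peptide_rule!r}")


@dataclass
class HingeStates:
    """State X / state Y / peptide models plus the generating transform.

    Domain 1 (residue ordinals ``domain1_idx`` of the hinge chain) is
    bitwise-identical between the two states; domain 2 differs by
    ``transform``.  ``complex_y`` is state Y with the peptide as chain B.
    """

    state_x: BackboneStructure
    state_y: BackboneStructure
    peptide: BackboneStructure
    transform: RigidTransform
    spec: HingeSpec
    helices: list[HelixSegment]
    domain1_idx: list[int]          # 0-based ordinals into the hinge chain
    domain2_idx: list[int]
    partition: np.ndarray           # helix/loop segment id per hinge residue
    report: dict = field(default_factory=dict)

    @property
    def complex_y(self) -> BackboneStructure:
        residues = [r.copy() for r in self.state_y.residues]
        residues += [r.copy() for r in self.peptide.residues]
        return BackboneStructure(residues)


def _helix_partition(n_res: int, helices: list[HelixSegment]) -> np.ndarray:
    """Segment id per residue: helix ordinal, loops merged into the
    preceding helix (leading residues into the first)."""
    part = np.zeros(n_res, dtype=int)
    current = 0
    for i in range(n_res):
        pos = i + 1
        for h_ord, h in enumerate(helices):
            if h.start <= pos <= h.end:
                current = h_ord
                break
        part[i] = current
    return part


def assemble_states(parent: BackboneStructure, spec: HingeSpec,
                    helices: list[HelixSegment] | None = None) -> HingeStates:
    """Build the state X / state Y / peptide triple from a parent scaffold.

    State X is the parent.  State Y keeps helices 1..p (and their internal
    loops) fixed and applies the pivot-shift transform to helices p+1..n;
    the loop between the domains is severed (its required replacement length
    is recorded in the report, no loop atoms are fabricated).  The peptide is
    the parent helix p+1 (``following_original``) or the moved copy of helix
    p (``preceding_copy``), emitted as chain B.
    """
    chains = parent.chain_ids()
    if len(chains) != 1:
        raise StructureError("parent scaffold must be a single chain")
    if helices is None:
        helices = detect_helices(parent)
    n_h = len(helices)
    if n_h < 4:
        raise StructureError(f"need >= 4 helices, found {n_h}")
    p = spec.pivot_index
    if not (1 < p < n_h):
        raise StructureError(
            f"pivot_index {p} must be interior (2..{n_h - 1})")
    pivot = helices[p - 1]
    if pivot.axis_dir is None:
        from .structure import fit_helix_axis
        pivot = fit_helix_axis(parent, pivot)
    transform = pivot_shift_transform(parent, pivot, spec.shift_s)

    chain = parent.chain(chains[0])
    n_res = len(chain)
    d1_end = helices[p - 1].end          # 1-based inclusive
    d2_start = helices[p].start
    domain1_idx = list(range(0, d1_end))
    domain2_idx = list(range(d2_start - 1, n_res))
    severed = list(range(d1_end, d2_start - 1))

    state_x = build_cb(BackboneStructure([r.copy() for r in chain]))
    y_res = []
    for i in domain1_idx:
        y_res.append(state_x.residues[i].copy())
    for i in domain2_idx:
        r = state_x.residues[i].copy()
        for k in r.coords:
            r.coords[k] = transform.apply(r.coords[k])
        y_res.append(r)
    state_y = BackboneStructure(y_res)

    if spec.peptide_rule == "following_original":
        src = helices[p]
        pep_res = [state_x.residues[i].copy()
                   for i in range(src.start - 1, src.end)]
    else:
        src = helices[p - 1]
        pep_res = []
        for i in range(src.start - 1, src.end):
            r = state_x.residues[i].copy()
            for k in r.coords:
                r.coords[k] = transform.apply(r.coords[k])
            pep_res.append(r)
    for r in pep_res:
        r.chain_id = "B"
    peptide = BackboneStructure(pep_res)

    partition = _helix_partition(n_res, helices)
    y_partition = partition[domain1_idx + domain2_idx]

    states = HingeStates(state_x, state_y, peptide, transform, spec,
                         helices, domain1_idx, domain2_idx, partition)

    # report: gap left by the severed loop, screw parameters, gate, clashes
    c_last = state_y.residues[len(domain1_idx) - 1].coords["C"]
    n_first = state_y.residues[len(domain1_idx)].coords["N"]
    gap = float(np.linalg.norm(n_first - c_last))
    _, axis, angle, slide, degenerate = screw_decompose(transform)
    gate = two_state_gate(states)
    states.report = {
        "loop_gap_A": gap,
        "severed_loop_residues": len(severed),
        "loop_feasible": loop_feasibility(gap, len(severed)),
        "screw_angle_deg": angle,
        "screw_slide_A": slide,
        "screw_degenerate": degenerate,
        "pivot_rmsd_warning": bool(transform.warning),
        "clash_x": clash_count(state_x),
        "clash_y": clash_count(state_y),
        "clash_complex": clash_count(states.complex_y),
        **gate,
    }
    return states


def two_state_gate(states: HingeStates) -> dict:
    """Apply the two-state selection logic with the surrogate contact energy.

    Selects a design only if (a) state X is lower in energy than the
    peptide-free state Y and (b) the state-Y complex is lower than state X
    plus the spatially separated peptide (whose isolated energy is zero by
    construction: a single rigid segment has no inter-segment contacts).
    """
    part_x = states.partition
    part_y = states.partition[states.domain1_idx + states.domain2_idx]
    n_pep = len(states.peptide)
    part_complex = np.concatenate([part_y, np.full(n_pep, part_x.max() + 1)])
    e_x = contact_energy(states.state_x, part_x)
    e_y = contact_energy(states.state_y, part_y)
    e_complex = contact_energy(states.complex_y, part_complex)
    e_pep = contact_energy(states.peptide, np.zeros(n_pep, int))
    pass_x_lower = e_x < e_y
    pass_complex_lower = e_complex < e_x + e_pep
    return {
        "e_state_x": e_x,
        "e_state_y": e_y,
        "e_complex_y": e_complex,
        "e_peptide": e_pep,
        "pass_x_lower": pass_x_lower,
        "pass_complex_lower": pass_complex_lower,
        "pass": bool(pass_x_lower and pass_complex_lower),
    }


# ---------------------------------------------------------------------------
# Label-site and staple-site selection

@dataclass
class SitePair:
    """A cross-domain residue pair with its CB-CB distance in each state."""

    res_i: int   # 1-based position in the hinge chain (domain 1)
    res_j: int   # 1-based position in the hinge chain (domain 2)
    d_x: float
    d_y: float

    @property
    def delta(self) -> float:
        return self.d_y - self.d_x


def _cb_arrays(states: HingeStates) -> tuple[np.ndarray, np.ndarray]:
    """CB coordinates of the hinge chain in state X and state Y order-aligned
    to residue ordinals 0..n-1 of the parent chain."""
    n = len(states.state_x)
    cb_x = states.state_x.coords_of("CB")
    cb_y = np.full((n, 3), np.nan)
    order = states.domain1_idx + states.domain2_idx
    cb_y_packed = states.state_y.coords_of("CB")
    for row, ordinal in enumerate(order):
        cb_y[ordinal] = cb_y_packed[row]
    return cb_x, cb_y


def _surface_mask(cb: np.ndarray, max_neighbors: int = 14,
                  radius: float = 10.0) -> np.ndarray:
    valid = ~np.isnan(cb[:, 0])
    pts = cb[valid]
    tree = cKDTree(pts)
    counts = np.array([len(tree.query_ball_point(p, radius)) - 1 for p in pts])
    mask = np.zeros(len(cb), bool)
    mask[np.flatnonzero(valid)] = counts <= max_neighbors
    return mask


def site_pairs(states: HingeStates, mode: str, top_k: int = 10) -> list[SitePair]:
    """Rank surface-exposed cross-domain label-site pairs by distance change.

    ``mode="increase"`` keeps pairs whose CB-CB distance grows from state X
    to state Y, ``"decrease"`` the opposite.  A residue qualifies as surface
    when its CB has at most 14 CB neighbours within 10 A in both states
    (burial proxy).  Pairs are ranked by |delta| descending; ties by smaller
    ``res_i`` then ``res_j``.
    """
    if mode not in ("increase", "decrease"):
        raise ValueError(f"mode must be 'increase' or 'decrease', got {mode!r}")
    cb_x, cb_y = _cb_arrays(states)
    surf = _surface_mask(cb_x) & _surface_mask(cb_y)
    pairs: list[SitePair] = []
    for i in states.domain1_idx:
        if not surf[i]:
            continue
        for j in states.domain2_idx:
            if not surf[j]:
                continue
            d_x = float(np.linalg.norm(cb_x[i] - cb_x[j]))
            d_y = float(np.linalg.norm(cb_y[i] - cb_y[j]))
            delta = d_y - d_x
            if mode == "increase" and delta <= 0:
                continue
            if mode == "decrease" and delta >= 0:
                continue
            pairs.append(SitePair(i + 1, j + 1, d_x, d_y))
    pairs.sort(key=lambda p: (-abs(p.delta), p.res_i, p.res_j))
    return pairs[:top_k]


def staple_candidates(states: HingeStates, lock_state: str = "X",
                      d_bond: tuple[float, float] = (3.5, 5.5),
                      d_excl: float = 10.0) -> list[SitePair]:
    """Cross-domain pairs able to form a state-selective disulfide staple.

    A pair qualifies when its CB-CB distance falls inside ``d_bond`` in the
    state to lock and exceeds ``d_excl`` in the other state, so the bond is
    geometrically possible in only one conformation.  Ranked by centrality
    of the in-range distance, then by index.
    """
    if lock_state not in ("X", "Y"):
        raise ValueError(f"lock_state must be 'X' or 'Y', got {lock_state!r}")
    cb_x, cb_y = _cb_arrays(states)
    mid = 0.5 * (d_bond[0] + d_bond[1])
    out: list[SitePair] = []
    for i in states.domain1_idx:
        for j in states.domain2_idx:
            d_x = float(np.linalg.norm(cb_x[i] - cb_x[j]))
            d_y = float(np.linalg.norm(cb_y[i] - cb_y[j]))
            d_lock, d_other = (d_x, d_y) if lock_state == "X" else (d_y, d_x)
            if d_bond[0] <= d_lock <= d_bond[1] and d_other > d_excl:
                out.append(SitePair(i + 1, j + 1, d_x, d_y))
    key_lock = (lambda p: p.d_x) if lock_state == "X" else (lambda p: p.d_y)
    out.sort(key=lambda p: (abs(key_lock(p) - mid), p.res_i, p.res_j))
    return out


def loop_feasibility(gap: float, n_loop_residues: int) -> bool:
    """Can ``n_loop_residues`` bridge a ``gap``?  True iff
    gap <= 3.8 x (n + 1) (fully extended CA virtual bonds)."""
    if gap < 0 or n_loop_residues < 0:
        raise ValueError("gap and loop length must be non-negative")
    return gap <= LOOP_STEP * (n_loop_residues + 1)
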