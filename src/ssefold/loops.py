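"""Loop construction: grow missing residues and close chain breaks by CCD.

SSE-only models leave loop residues unmodeled.  To produce complete models
the builder (1) trims one residue from each SSE end to gain slack, (2) grows
missing residues with phi/psi angles drawn from per-residue-type
Ramachandran tables, picking the best of K candidate conformations by a
clash + burial + closure-bias score, (3) closes each chain break by cyclic
coordinate descent (CCD): one backbone dihedral at a time is set to the
closed-form angle that minimizes the RMSD between a grown copy of the
downstream anchor residue's N, CA, C atoms and their fixed positions, and
(4) force-closes stubborn loops by re-growing with fresh angles.  SSE atoms
are never moved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import LoopSettings
from .geometry import (
    ANGLE_CA_C_N, ANGLE_C_N_CA, ANGLE_N_CA_C, ANGLE_CA_C_O, ANGLE_N_CA_CB,
    BOND_C_N, BOND_C_O, BOND_CA_C, BOND_CA_CB, BOND_N_CA,
    TORSION_C_N_CA_CB, AA_CODES, CA, CB, C, MIN_SSE_LENGTH, N, O,
    ProteinModel, place_atom,
)


class LoopError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Ramachandran tables (analytic mixtures over 10-degree bins)
# ---------------------------------------------------------------------------

_BIN = 10.0
_EDGES = np.arange(-180.0, 181.0, _BIN)
_CENTERS = (_EDGES[:-1] + _EDGES[1:]) / 2.0


def _gauss2(phi0, psi0, sigma):
    """Unnormalized wrapped Gaussian bump on the (phi, psi) grid."""
    def wrap(d):
        return (d + 180.0) % 360.0 - 180.0
    dphi = wrap(_CENTERS[:, None] - phi0)
    dpsi = wrap(_CENTERS[None, :] - psi0)
    return np.exp(-(dphi**2 + dpsi**2) / (2.0 * sigma**2))


@dataclass
class RamachandranTable:
    """Per amino acid type: (36, 36) coil-state (phi, psi) probability grid.

    Grids are analytic mixtures of Gaussians around the canonical basins
    (right-handed alpha, beta, left-handed alpha) rather than a PDB survey;
    glycine is broader and symmetric, proline restricted in phi.
    """

    grids: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "RamachandranTable":
        grids = {}
        generic = (
            0.50 * _gauss2(-63, -43, 18)
            + 0.42 * _gauss2(-120, 130, 30)
            + 0.08 * _gauss2(60, 45, 15)
        )
        gly = (
            0.30 * _gauss2(-63, -43, 25)
            + 0.30 * _gauss2(-120, 130, 35)
            + 0.30 * _gauss2(63, 43, 25)
            + 0.10 * np.ones((36, 36))
        )
        pro = 0.55 * _gauss2(-65, 150, 15) + 0.45 * _gauss2(-65, -30, 15)
        for aa in AA_CODES:
            if aa == "G":
                grid = gly
            elif aa == "P":
                grid = pro
            else:
                grid = generic
            grids[aa] = grid / grid.sum()
        return cls(grids)

    def sample(self, aa: str, rng):
        """Draw (phi, psi) in degrees: a grid bin plus uniform in-bin jitter."""
        grid = self.grids[aa]
        flat = rng.choice(grid.size, p=grid.ravel())
        i, j = np.unravel_index(int(flat), grid.shape)
        phi = _CENTERS[i] + rng.uniform(-_BIN / 2, _BIN / 2)
        psi = _CENTERS[j] + rng.uniform(-_BIN / 2, _BIN / 2)
        return float(phi), float(psi)


# ---------------------------------------------------------------------------
# Built structures
# ---------------------------------------------------------------------------


@dataclass
class Loop:
    """One stretch of grown residues.

    kind: "bridge" (between two SSEs, CCD-closable), "tail_n" or "tail_c".
    ``first``/``last`` are 1-based bounds of the grown residues (may be an
    empty range for a direct junction).  For bridges, ``anchor_virtual``
    holds the grown copy of the downstream residue's (N, CA, C) and
    ``anchor_target`` their fixed positions.
    """

    kind: str
    first: int
    last: int
    upstream_res: int | None = None     # SSE residue the loop grows from
    downstream_res: int | None = None   # SSE residue it must reach (bridge)
    anchor_virtual: np.ndarray | None = None
    anchor_target: np.ndarray | None = None
    closed: bool = False
    closure_distance: float = float("nan")
    forced: bool = False

    @property
    def n_res(self) -> int:
        return max(0, self.last - self.first + 1)

    def anchor_rmsd(self) -> float:
        d = self.anchor_virtual - self.anchor_target
        return float(np.sqrt((d**2).sum(axis=1).mean()))


@dataclass
class BuiltStructure:
    """A complete backbone: every residue has coordinates.

    ``coords`` is (L, 5, 3) in N, CA, C, O, CB order; ``sse_mask`` marks
    residues that belong to (trimmed) SSEs and are never moved.
    """

    sequence: str
    coords: np.ndarray
    sse_mask: np.ndarray
    loops: list = field(default_factory=list)

    def modeled_indices(self):
        return np.arange(1, len(self.sequence) + 1)


# ---------------------------------------------------------------------------
# Trim
# ---------------------------------------------------------------------------


def trim_sses(model: ProteinModel) -> ProteinModel:
    """Shorten every SSE by one residue at each end to ease loop closure.

    SSEs that would fall below their minimum length are left untrimmed.
    Retained residue coordinates are unchanged (sub-array of the original).
    """
    new = []
    for sse in model.sses:
        if sse.n_res >= MIN_SSE_LENGTH[sse.ss_type] + 2:
            trimmed = type(sse)(
                sse.ss_type, sse.first + 1, sse.last - 1, sse.sequence[1:-1],
                sse.body_frame, sse.coords[1:-1],
            )
            new.append(trimmed)
        else:
            new.append(sse)
    return model.replace_sses(new)


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------


def _finish_residue(coords, i, psi):
    """Place O and CB of residue i once N, CA, C are set."""
    coords[i, O] = place_atom(
        coords[i, N], coords[i, CA], coords[i, C],
        BOND_C_O, ANGLE_CA_C_O, psi + 180.0,
    )
    coords[i, CB] = place_atom(
        coords[i, C], coords[i, N], coords[i, CA],
        BOND_CA_CB, ANGLE_N_CA_CB, TORSION_C_N_CA_CB,
    )


def _grow_forward(coords, start, count, dihedrals, prev_psi):
    """Grow ``count`` residues after 0-based residue ``start`` (which has
    N, CA, C set) using [(phi, psi)] pairs; returns psi of the last grown
    residue. ``prev_psi`` is the sampled psi of the anchor residue."""
    psi_prev = prev_psi
    for k in range(count):
        i = start + 1 + k
        phi, psi = dihedrals[k]
        coords[i, N] = place_atom(
            coords[i - 1, N], coords[i - 1, CA], coords[i - 1, C],
            BOND_C_N, ANGLE_CA_C_N, psi_prev,
        )
        coords[i, CA] = place_atom(
            coords[i - 1, CA], coords[i - 1, C], coords[i, N],
            BOND_N_CA, ANGLE_C_N_CA, 180.0,
        )
        coords[i, C] = place_atom(
            coords[i - 1, C], coords[i, N], coords[i, CA],
            BOND_CA_C, ANGLE_N_CA_C, phi,
        )
        _finish_residue(coords, i, psi)
        psi_prev = psi
    return psi_prev


def _virtual_anchor(coords, last_loop_idx, psi_last, phi_next):
    """Grown copy of the downstream residue's (N, CA, C) continuing the
    chain past the last loop residue."""
    n_v = place_atom(
        coords[last_loop_idx, N], coords[last_loop_idx, CA],
        coords[last_loop_idx, C], BOND_C_N, ANGLE_CA_C_N, psi_last,
    )
    ca_v = place_atom(
        coords[last_loop_idx, CA], coords[last_loop_idx, C], n_v,
        BOND_N_CA, ANGLE_C_N_CA, 180.0,
    )
    c_v = place_atom(
        coords[last_loop_idx, C], n_v, ca_v, BOND_CA_C, ANGLE_N_CA_C, phi_next,
    )
    return np.stack([n_v, ca_v, c_v])


def _grow_backward(coords, start, count, dihedrals, phi_start):
    """Grow ``count`` residues before 0-based residue ``start`` (N-terminal
    tail), moving upstream; dihedrals[k] = (phi, psi) of residue start-1-k;
    ``phi_start`` is the sampled phi of the anchor residue itself (its own
    phi is undefined in an isolated SSE and positions the first grown C)."""
    for k in range(count):
        j = start - k  # residue below which we grow
        i = j - 1
        phi_j = phi_start if k == 0 else dihedrals[k - 1][0]
        psi_i = dihedrals[k][1]
        coords[i, C] = place_atom(
            coords[j, C], coords[j, CA], coords[j, N],
            BOND_C_N, ANGLE_C_N_CA, phi_j,
        )
        coords[i, CA] = place_atom(
            coords[j, CA], coords[j, N], coords[i, C],
            BOND_CA_C, ANGLE_CA_C_N, 180.0,
        )
        coords[i, N] = place_atom(
            coords[j, N], coords[i, C], coords[i, CA],
            BOND_N_CA, ANGLE_N_CA_C, psi_i,
        )
        _finish_residue(coords, i, psi_i)


def _candidate_score(structure_cb, loop_cb, loop_bias):
    """Clash + burial + closure-bias score of one growth candidate (lower
    is better).  Clash: quadratic CB overlap below 3 A against the already
    placed residues; burial: mild penalty on crowding (>12 neighbors)."""
    score = loop_bias
    if len(structure_cb) and len(loop_cb):
        d = np.linalg.norm(loop_cb[:, None] - structure_cb[None], axis=-1)
        overlap = np.maximum(0.0, 3.0 - d)
        score += 10.0 * float((overlap**2).sum())
        crowd = (d < 10.0).sum(axis=1)
        score += float(np.maximum(0, crowd - 12).sum())
    return score


def grow_loops(model: ProteinModel, rama: RamachandranTable, rng,
               settings: LoopSettings = LoopSettings()) -> BuiltStructure:
    """Grow every missing residue; returns a complete backbone.

    Per loop, ``settings.growth_candidates`` candidate dihedral sets are
    sampled and the best by clash + burial + closure-bias (the distance
    left to the downstream anchor) is kept.
    """
    if not model.sses:
        raise LoopError("model has no SSEs")
    L = len(model.sequence)
    coords = np.full((L, 5, 3), np.nan)
    sse_mask = model.covered_mask()
    for sse in model.sses:
        coords[sse.first - 1 : sse.last] = sse.coords
    built = BuiltStructure(model.sequence, coords, sse_mask)

    placed_cb = [sse.coords[:, CB, :] for sse in model.sses]

    def grown_cb(lo, hi):
        return coords[lo:hi, CB, :]

    # bridges between adjacent SSEs
    for pair in range(model.n_sses - 1):
        up = model.sses[pair]
        down = model.sses[pair + 1]
        first, last = up.last + 1, down.first - 1
        n_loop = last - first + 1
        loop = Loop(
            "bridge", first, last,
            upstream_res=up.last, downstream_res=down.first,
            anchor_target=down.coords[0, (N, CA, C), :].copy(),
        )
        best = None
        for _ in range(max(1, settings.growth_candidates)):
            psi_anchor = rama.sample(model.sequence[up.last - 1], rng)[1]
            dihedrals = [
                rama.sample(model.sequence[i - 1], rng)
                for i in range(first, last + 1)
            ]
            phi_next = rama.sample(model.sequence[down.first - 1], rng)[0]
            trial = coords.copy()
            if n_loop > 0:
                psi_last = _grow_forward(
                    trial, up.last - 1, n_loop, dihedrals, psi_anchor
                )
                last_idx = last - 1
            else:
                psi_last = psi_anchor
                last_idx = up.last - 1
            virtual = _virtual_anchor(trial, last_idx, psi_last, phi_next)
            diff = virtual - loop.anchor_target
            bias = float(np.sqrt((diff**2).sum(axis=1).mean()))
            cand_cb = trial[first - 1 : last, CB, :] if n_loop else np.zeros((0, 3))
            score = _candidate_score(
                np.concatenate(placed_cb) if placed_cb else np.zeros((0, 3)),
                cand_cb, bias,
            )
            if best is None or score < best[0]:
                best = (score, trial, virtual, psi_anchor, dihedrals, phi_next)
        _, trial, virtual, psi_anchor, dihedrals, phi_next = best
        coords[first - 1 : last] = trial[first - 1 : last]
        loop.anchor_virtual = virtual
        loop.closure_distance = loop.anchor_rmsd()
        built.loops.append(loop)
        if n_loop > 0:
            placed_cb.append(grown_cb(first - 1, last).copy())

    # terminal tails (no downstream anchor, grown without CCD)
    first_sse, last_sse = model.sses[0], model.sses[-1]
    if first_sse.first > 1:
        first, last = 1, first_sse.first - 1
        best = None
        for _ in range(max(1, settings.growth_candidates)):
            phi_start = rama.sample(model.sequence[first_sse.first - 1], rng)[0]
            dihedrals = [
                rama.sample(model.sequence[last - k - 1], rng)
                for k in range(last - first + 1)
            ]
            trial = coords.copy()
            _grow_backward(trial, first_sse.first - 1, last - first + 1,
                           dihedrals, phi_start)
            score = _candidate_score(
                np.concatenate(placed_cb), trial[first - 1 : last, CB, :], 0.0
            )
            if best is None or score < best[0]:
                best = (score, trial)
        coords[first - 1 : last] = best[1][first - 1 : last]
        built.loops.append(Loop("tail_n", first, last, closed=True,
                                closure_distance=0.0))
        placed_cb.append(grown_cb(first - 1, last).copy())
    if last_sse.last < L:
        first, last = last_sse.last + 1, L
        best = None
        for _ in range(max(1, settings.growth_candidates)):
            psi_anchor = rama.sample(model.sequence[last_sse.last - 1], rng)[1]
            dihedrals = [
                rama.sample(model.sequence[i - 1], rng)
                for i in range(first, last + 1)
            ]
            trial = coords.copy()
            _grow_forward(trial, last_sse.last - 1, last - first + 1,
                          dihedrals, psi_anchor)
            score = _candidate_score(
                np.concatenate(placed_cb), trial[first - 1 : last, CB, :], 0.0
            )
            if best is None or score < best[0]:
                best = (score, trial)
        coords[first - 1 : last] = best[1][first - 1 : last]
        built.loops.append(Loop("tail_c", first, last, closed=True,
                                closure_distance=0.0))
    return built


# ---------------------------------------------------------------------------
# CCD closure
# ---------------------------------------------------------------------------


def _rotate_about(points, origin, axis, theta):
    rel = points - origin
    par = np.outer(rel @ axis, axis)
    perp = rel - par
    cross = np.cross(axis, perp)
    return origin + par + perp * np.cos(theta) + cross * np.sin(theta)


def _optimal_angle(mobile, fixed, origin, axis) -> float:
    """Closed-form CCD angle: argmin over theta of sum |R_theta m - f|^2."""
    rel_m = mobile - origin
    rel_f = fixed - origin
    par_m = np.outer(rel_m @ axis, axis)
    r = rel_m - par_m
    s = rel_f - par_m  # fixed relative to each mobile point's axis foot
    a = float((r * s).sum())
    b = float((np.cross(axis, r) * s).sum())
    if abs(a) < 1e-15 and abs(b) < 1e-15:
        return 0.0
    return float(np.arctan2(b, a))


def _ccd_dihedrals(loop: Loop):
    """Adjustable dihedrals of a bridge loop, N- to C-terminal order.

    Each item is (axis origin (res, atom), axis end (res, atom), mobile
    spec); residues are 0-based.  The anchor residue's psi comes first
    (moves all loop atoms but no SSE atom), then phi and psi of every loop
    residue; the virtual anchor copy is always mobile.
    """
    up = loop.upstream_res - 1
    lo = loop.first - 1
    hi = loop.last  # exclusive
    rots = [((up, CA), (up, C), [("res_range", lo, hi)])]
    for i in range(lo, hi):
        rots.append(((i, N), (i, CA),
                     [("atoms", i, (C, O, CB)), ("res_range", i + 1, hi)]))
        rots.append(((i, CA), (i, C),
                     [("atoms", i, (O,)), ("res_range", i + 1, hi)]))
    return rots


def _apply_ccd_rotation(structure, loop, spec, origin, axis, theta):
    coords = structure.coords
    for kind, *args in spec:
        if kind == "res_range":
            lo, hi = args
            if hi > lo:
                flat = coords[lo:hi].reshape(-1, 3)
                coords[lo:hi] = _rotate_about(flat, origin, axis, theta).reshape(
                    hi - lo, 5, 3
                )
        else:
            i, atoms = args
            sel = list(atoms)
            coords[i, sel, :] = _rotate_about(coords[i, sel, :], origin, axis, theta)
    loop.anchor_virtual = _rotate_about(loop.anchor_virtual, origin, axis, theta)


def ccd_close(structure: BuiltStructure,
              tolerance: float = 0.08, max_sweeps: int = 200):
    """Close every bridge loop by cyclic coordinate descent.

    Sweeps over the adjustable dihedrals, setting each to the closed-form
    optimum for the 3-atom anchor RMSD; stops per loop when the RMSD is
    within ``tolerance`` or after ``max_sweeps``.  The anchor RMSD never
    increases within a sweep step.  Returns (structure, {loop: distance}).
    """
    distances = {}
    for loop in structure.loops:
        if loop.kind != "bridge":
            continue
        rmsd = loop.anchor_rmsd()
        if rmsd <= tolerance:
            loop.closed = True
            loop.closure_distance = rmsd
            distances[(loop.first, loop.last)] = rmsd
            continue
        for _ in range(max_sweeps):
            for (ro, ao), (re, ae), spec in _ccd_dihedrals(loop):
                origin = structure.coords[ro, ao].copy()
                axis = structure.coords[re, ae] - origin
                axis = axis / np.linalg.norm(axis)
                theta = _optimal_angle(loop.anchor_virtual, loop.anchor_target,
                                       origin, axis)
                if theta == 0.0:
                    continue
                _apply_ccd_rotation(structure, loop, spec, origin, axis, theta)
            # the downstream residue's phi: spin the virtual C about the
            # virtual N-CA axis (the chain itself fixes everything else)
            origin = loop.anchor_virtual[0].copy()
            axis = loop.anchor_virtual[1] - origin
            axis = axis / np.linalg.norm(axis)
            theta = _optimal_angle(loop.anchor_virtual[2:3],
                                   loop.anchor_target[2:3], origin, axis)
            if theta != 0.0:
                loop.anchor_virtual[2] = _rotate_about(
                    loop.anchor_virtual[2:3], origin, axis, theta
                )[0]
            rmsd = loop.anchor_rmsd()
            if rmsd <= tolerance:
                break
        loop.closure_distance = rmsd
        loop.closed = rmsd <= tolerance
        distances[(loop.first, loop.last)] = rmsd
    return structure, distances


def force_close(structure: BuiltStructure, model: ProteinModel,
                rama: RamachandranTable, rng,
                settings: LoopSettings = LoopSettings()) -> BuiltStructure:
    """Re-grow and re-close loops that CCD left open.

    Up to ``settings.force_rounds`` rounds of fresh Ramachandran growth
    followed by CCD; if still open, the conformation with the smallest
    closure distance is kept and the loop flagged ``forced``.
    """
    for loop in structure.loops:
        if loop.kind != "bridge" or loop.closed:
            continue
        best = (loop.closure_distance,
                structure.coords[loop.first - 1 : loop.last].copy(),
                loop.anchor_virtual.copy())
        up = next(s for s in model.sses if s.last == loop.upstream_res)
        for _ in range(settings.force_rounds):
            n_loop = loop.n_res
            psi_anchor = rama.sample(model.sequence[up.last - 1], rng)[1]
            dihedrals = [
                rama.sample(model.sequence[i - 1], rng)
                for i in range(loop.first, loop.last + 1)
            ]
            phi_next = rama.sample(
                model.sequence[loop.downstream_res - 1], rng
            )[0]
            if n_loop > 0:
                psi_last = _grow_forward(
                    structure.coords, up.last - 1, n_loop, dihedrals, psi_anchor
                )
                last_idx = loop.last - 1
            else:
                psi_last = psi_anchor
                last_idx = up.last - 1
            loop.anchor_virtual = _virtual_anchor(
                structure.coords, last_idx, psi_last, phi_next
            )
            ccd_close(structure, settings.ccd_tolerance, settings.ccd_max_sweeps)
            if loop.closure_distance < best[0]:
                best = (loop.closure_distance,
                        structure.coords[loop.first - 1 : loop.last].copy(),
                        loop.anchor_virtual.copy())
            if loop.closed:
                break
        if not loop.closed:
            loop.closure_distance = best[0]
            structure.coords[loop.first - 1 : loop.last] = best[1]
            loop.anchor_virtual = best[2]
            loop.forced = True
    return structure


def build_all_loops(model: ProteinModel, rng,
                    rama: RamachandranTable | None = None,
                    settings: LoopSettings = LoopSettings()) -> BuiltStructure:
    """Convenience pipeline: trim, grow, CCD-close, force-close."""
    if rama is None:
        rama = RamachandranTable.default()
    trimmed = trim_sses(model)
    built = grow_loops(trimmed, rama, rng, settings)
    ccd_close(built, settings.ccd_tolerance, settings.ccd_max_sweeps)
    force_close(built, trimmed, rama, rng, settings)
    return built
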