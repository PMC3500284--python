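"""Core structural types: rigid transforms, idealized SSEs, protein models.

A protein model here is an ordered collection of secondary structure
elements (SSEs) placed as rigid bodies over one amino acid sequence.  Each
SSE carries idealized backbone geometry (N, CA, C, O, CB per residue;
glycine gets a pseudo-CB placed with the same tetrahedral geometry so all
pair potentials treat residues uniformly) built from canonical dihedral
angles, plus a rigid body frame relating the canonical template to its
current placement in space.  Loop residues are intentionally absent: the
conformational search moves whole SSEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

# ---------------------------------------------------------------------------
# Constants: residues, atoms, ideal covalent geometry
# ---------------------------------------------------------------------------

AA_CODES = "ACDEFGHIKLMNPQRSTVWY"

#: atom slot order in every coordinate array
ATOMS = ("N", "CA", "C", "O", "CB")
N, CA, C, O, CB = range(5)

# Backbone bond lengths (Angstrom) and angles (degrees) -- textbook values.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521

ANGLE_N_CA_C = 109.5
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.4
TORSION_C_N_CA_CB = -122.6  # improper fixing L-chirality of the CB branch

#: ideal (phi, psi, omega) in degrees per SSE type
IDEAL_DIHEDRALS = {
    "helix": (-57.0, -47.0, 180.0),
    "strand": (-135.0, 135.0, 180.0),
}

#: minimum SSE lengths in residues
MIN_SSE_LENGTH = {"helix": 5, "strand": 3}

#: nominal per-residue rise along the SSE axis (Angstrom), for documentation
#: and placement heuristics; actual built geometry follows the dihedrals.
NOMINAL_RISE = {"helix": 1.50, "strand": 3.40}


class GeometryError(ValueError):
    """Raised on invalid geometric input (bad segment, bad transform...)."""


_EYE3 = np.eye(3)


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float)
        tra = np.asarray(self.translation, dtype=float).reshape(3)
        if rot.shape != (3, 3):
            raise GeometryError("rotation must be 3x3")
        if abs(rot @ rot.T - _EYE3).max() > 1e-8:
            raise GeometryError("rotation must be orthonormal")
        det = (
            rot[0, 0] * (rot[1, 1] * rot[2, 2] - rot[1, 2] * rot[2, 1])
            - rot[0, 1] * (rot[1, 0] * rot[2, 2] - rot[1, 2] * rot[2, 0])
            + rot[0, 2] * (rot[1, 0] * rot[2, 1] - rot[1, 1] * rot[2, 0])
        )
        if abs(det - 1.0) > 1e-8:
            raise GeometryError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @classmethod
    def _trusted(cls, rotation, translation) -> "RigidTransform":
        """Construction bypassing validation, for internally derived
        transforms that are proper by arithmetic (compose, inverse...)."""
        self = object.__new__(cls)
        object.__setattr__(self, "rotation", rotation)
        object.__setattr__(self, "translation", translation)
        return self

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls._trusted(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls._trusted(np.eye(3), np.asarray(t, dtype=float).reshape(3))

    @classmethod
    def from_rotation_about(cls, axis, angle_rad, center=None) -> "RigidTransform":
        """Rotation by ``angle_rad`` about ``axis`` through ``center``."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        K = np.array(
            [
                [0.0, -axis[2], axis[1]],
                [axis[2], 0.0, -axis[0]],
                [-axis[1], axis[0], 0.0],
            ]
        )
        R = (
            np.eye(3)
            + np.sin(angle_rad) * K
            + (1.0 - np.cos(angle_rad)) * (K @ K)
        )
        if center is None:
            t = np.zeros(3)
        else:
            center = np.asarray(center, dtype=float)
            t = center - R @ center
        return cls._trusted(R, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of points."""
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first, then ``self``)."""
        return RigidTransform._trusted(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform._trusted(
            self.rotation.T, -self.rotation.T @ self.translation
        )


# ---------------------------------------------------------------------------
# Backbone construction (NeRF) and the canonical SSE template
# ---------------------------------------------------------------------------


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given chain a-b-c, |c-d|, angle(b,c,d) and torsion(a,b,c,d).

    Standard natural-extension reference frame construction.
    """
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        # colinear a-b-c: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        norm = np.linalg.norm(n)
    n = n / norm
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), -np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (radians) of the four points, IUPAC convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.arctan2(y, x))


def build_backbone(phis, psis, omegas) -> np.ndarray:
    """Forward-build an n-residue backbone from per-residue dihedrals.

    ``phis[0]`` is unused (no upstream peptide bond); ``psis[-1]`` and
    ``omegas[-1]`` define only the final O placement.  Returns an
    (n, 5, 3) array in an arbitrary frame.
    """
    n_res = len(phis)
    coords = np.zeros((n_res, 5, 3))
    # seed residue 0 in the xy-plane
    coords[0, N] = [0.0, 0.0, 0.0]
    coords[0, CA] = [BOND_N_CA, 0.0, 0.0]
    ang = np.deg2rad(ANGLE_N_CA_C)
    coords[0, C] = coords[0, CA] + BOND_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0]
    )
    for i in range(1, n_res):
        coords[i, N] = place_atom(
            coords[i - 1, N], coords[i - 1, CA], coords[i - 1, C],
            BOND_C_N, ANGLE_CA_C_N, psis[i - 1],
        )
        coords[i, CA] = place_atom(
            coords[i - 1, CA], coords[i - 1, C], coords[i, N],
            BOND_N_CA, ANGLE_C_N_CA, omegas[i - 1],
        )
        coords[i, C] = place_atom(
            coords[i - 1, C], coords[i, N], coords[i, CA],
            BOND_CA_C, ANGLE_N_CA_C, phis[i],
        )
    for i in range(n_res):
        psi = psis[i]
        coords[i, O] = place_atom(
            coords[i, N], coords[i, CA], coords[i, C],
            BOND_C_O, ANGLE_CA_C_O, psi + 180.0,
        )
        coords[i, CB] = place_atom(
            coords[i, C], coords[i, N], coords[i, CA],
            BOND_CA_CB, ANGLE_N_CA_CB, TORSION_C_N_CA_CB,
        )
    return coords


def _regular_axis(ca: np.ndarray) -> np.ndarray:
    """Axis direction of a geometrically regular CA trace, oriented N->C.

    For a regular helix or strand the second differences of the CA positions
    are perpendicular to the screw axis, so the axis spans the null space of
    their scatter matrix; the end-to-end vector projected into that subspace
    breaks the remaining degeneracy.  Exact for ideal repeats, robust for
    near-ideal ones.
    """
    s = np.diff(ca, n=2, axis=0)
    if len(s) == 0:  # 2 residues: fall back to the bond direction
        v = ca[-1] - ca[0]
        return v / np.linalg.norm(v)
    M = s.T @ s
    w, V = np.linalg.eigh(M)
    # null-ish space: eigenvectors with eigenvalue < 1e-6 * largest (min 1)
    cut = max(w[-1] * 1e-6, 1e-12)
    null = V[:, w < cut]
    if null.shape[1] == 0:
        null = V[:, :1]
    e2e = ca[-1] - ca[0]
    axis = null @ (null.T @ e2e)
    nrm = np.linalg.norm(axis)
    if nrm < 1e-9:  # pathological: fall back to smallest eigenvector
        axis = V[:, 0]
        nrm = 1.0
    axis = axis / np.linalg.norm(axis)
    if axis @ e2e < 0:
        axis = -axis
    return axis


@lru_cache(maxsize=None)
def _canonical_template(ss_type: str, n_res: int) -> np.ndarray:
    """Idealized SSE coordinates in the canonical frame.

    Canonical frame: CA centroid at the origin, principal axis along +z with
    the first residue at negative z, and the in-plane orientation fixed by
    mapping the axis-perpendicular component of the first CA onto +x.
    Read-only cached array.
    """
    phi, psi, omega = IDEAL_DIHEDRALS[ss_type]
    coords = build_backbone([phi] * n_res, [psi] * n_res, [omega] * n_res)
    ca = coords[:, CA, :]
    centroid = ca.mean(axis=0)
    centered = ca - centroid
    axis = _regular_axis(ca)
    # x-direction: first CA's perpendicular component (fall back if ~0)
    perp = centered[0] - (centered[0] @ axis) * axis
    if np.linalg.norm(perp) < 1e-9:
        perp = np.array([1.0, 0.0, 0.0]) - axis[0] * axis
    x = perp / np.linalg.norm(perp)
    y = np.cross(axis, x)
    R = np.stack([x, y, axis])  # rows map world x,y,z onto canonical axes
    out = (coords - centroid) @ R.T
    # re-center the frame on the true screw axis: Kasa circle fit of the CA
    # positions in the axis-normal plane (the CA centroid of a partial turn
    # lies off-axis), then shift so the axis passes through the origin
    xy = out[:, CA, :2]
    A = np.column_stack([2 * xy, np.ones(len(xy))])
    b = (xy**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    out[:, :, 0] -= sol[0]
    out[:, :, 1] -= sol[1]
    out.setflags(write=False)
    return out


def canonical_template(ss_type: str, n_res: int) -> np.ndarray:
    if ss_type not in IDEAL_DIHEDRALS:
        raise GeometryError(f"unknown SSE type {ss_type!r}")
    return _canonical_template(ss_type, n_res)


@lru_cache(maxsize=None)
def template_axis_length(ss_type: str, n_res: int) -> float:
    """z-extent of the canonical template's CA trace (Angstrom)."""
    tpl = canonical_template(ss_type, n_res)
    z = tpl[:, CA, 2]
    return float(z.max() - z.min())


# ---------------------------------------------------------------------------
# SSE
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SSE:
    """A placed idealized secondary structure element.

    ``coords`` has shape (n_res, 5, 3) with atom order N, CA, C, O, CB and is
    always exactly ``body_frame`` applied to the canonical template.  SSEs
    are immutable; moves produce new instances.
    """

    ss_type: str
    first: int
    last: int
    sequence: str
    body_frame: RigidTransform
    coords: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.last < self.first:
            raise GeometryError("last < first")
        if len(self.sequence) != self.n_res:
            raise GeometryError("sequence length does not match bounds")

    @property
    def n_res(self) -> int:
        return self.last - self.first + 1

    @property
    def residue_indices(self) -> range:
        return range(self.first, self.last + 1)

    def axis(self):
        """(center, unit direction N->C, length) of the SSE axis."""
        cached = self.__dict__.get("_axis")
        if cached is None:
            R = self.body_frame.rotation
            cached = (
                self.body_frame.translation.copy(),
                R[:, 2].copy(),
                template_axis_length(self.ss_type, self.n_res),
            )
            object.__setattr__(self, "_axis", cached)
        return cached

    def axis_endpoints(self):
        center, direction, length = self.axis()
        half = 0.5 * length * direction
        return center - half, center + half

    def transformed(self, t: RigidTransform) -> "SSE":
        frame = t.compose(self.body_frame)
        return SSE(
            self.ss_type, self.first, self.last, self.sequence,
            frame, frame.apply(canonical_template(self.ss_type, self.n_res)),
        )

    def with_bounds(self, first: int, last: int, sequence: str) -> "SSE":
        """Same body frame, new bounds (used by resize/split moves)."""
        tpl = canonical_template(self.ss_type, last - first + 1)
        return SSE(
            self.ss_type, first, last, sequence,
            self.body_frame, self.body_frame.apply(tpl),
        )


def build_ideal_sse(sequence: str, first: int, last: int, ss_type: str) -> SSE:
    """Build an idealized SSE in the canonical frame.

    ``sequence`` is the amino acid segment covering ``first..last`` (1-based
    inclusive).  Deterministic: identical inputs give bitwise-identical
    coordinates.
    """
    if ss_type not in IDEAL_DIHEDRALS:
        raise GeometryError(f"unknown SSE type {ss_type!r}")
    n_res = last - first + 1
    if first < 1:
        raise GeometryError("residue indices are 1-based")
    if len(sequence) != n_res:
        raise GeometryError("segment length does not match bounds")
    if n_res < MIN_SSE_LENGTH[ss_type]:
        raise GeometryError(
            f"{ss_type} of length {n_res} below minimum {MIN_SSE_LENGTH[ss_type]}"
        )
    bad = set(sequence.upper()) - set(AA_CODES)
    if bad:
        raise GeometryError(f"unknown residue code(s): {sorted(bad)}")
    tpl = canonical_template(ss_type, n_res)
    return SSE(
        ss_type, first, last, sequence.upper(),
        RigidTransform.identity(), tpl.copy(),
    )


def apply_transform(sse: SSE, t: RigidTransform) -> SSE:
    return sse.transformed(t)


def sse_axis(sse: SSE):
    return sse.axis()


def derive_frame(coords: np.ndarray, ss_type: str) -> RigidTransform:
    """Recover the body frame of an SSE from its coordinates (Kabsch fit)."""
    n_res = coords.shape[0]
    tpl = canonical_template(ss_type, n_res).reshape(-1, 3)
    pts = coords.reshape(-1, 3)
    R, t = kabsch_fit(tpl, pts)
    return RigidTransform(R, t)


def kabsch_fit(source: np.ndarray, target: np.ndarray):
    """Optimal proper rotation R and translation t with R@source+t ~= target."""
    sc = source.mean(axis=0)
    tc = target.mean(axis=0)
    H = (source - sc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ sc
    return R, t


# ---------------------------------------------------------------------------
# ProteinModel
# ---------------------------------------------------------------------------


@dataclass
class ProteinModel:
    """Ordered, non-overlapping SSEs over one sequence.

    The object the conformational search mutates; mutation is by value
    (``replace_sses`` returns a new model sharing untouched SSEs).
    """

    sequence: str
    sses: list
    provenance: str = ""

    def __post_init__(self):
        self.sses = sorted(self.sses, key=lambda s: s.first)
        prev_last = 0
        for sse in self.sses:
            if sse.first <= prev_last:
                raise GeometryError("SSEs overlap in sequence")
            if sse.last > len(self.sequence):
                raise GeometryError("SSE extends past sequence end")
            seg = self.sequence[sse.first - 1 : sse.last]
            if seg.upper() != sse.sequence.upper():
                raise GeometryError(
                    f"SSE segment {sse.sequence} != sequence[{sse.first}:{sse.last}]"
                )
            prev_last = sse.last

    # -- content -----------------------------------------------------------

    @property
    def n_sses(self) -> int:
        return len(self.sses)

    def modeled_indices(self) -> np.ndarray:
        """Sorted 1-based indices of residues present in the model."""
        if not self.sses:
            return np.zeros(0, dtype=int)
        return np.concatenate([np.arange(s.first, s.last + 1) for s in self.sses])

    def covered_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.sequence), dtype=bool)
        for s in self.sses:
            mask[s.first - 1 : s.last] = True
        return mask

    def atom_coords(self, atom: int) -> np.ndarray:
        """Coordinates of one backbone atom slot for all modeled residues."""
        if not self.sses:
            return np.zeros((0, 3))
        return np.concatenate([s.coords[:, atom, :] for s in self.sses])

    def completeness(self, pool_mask: np.ndarray) -> float:
        """Fraction of pool-covered residues represented in this model."""
        denom = int(pool_mask.sum())
        if denom == 0:
            return 1.0
        return float((self.covered_mask() & pool_mask).sum() / denom)

    # -- editing -----------------------------------------------------------

    def replace_sses(self, new_sses) -> "ProteinModel":
        return ProteinModel(self.sequence, list(new_sses), self.provenance)

    def without(self, index: int) -> "ProteinModel":
        keep = [s for i, s in enumerate(self.sses) if i != index]
        return self.replace_sses(keep)

    def overlaps(self, first: int, last: int) -> bool:
        return any(not (last < s.first or first > s.last) for s in self.sses)

    # -- chain breaks ------------------------------------------------------

    def chain_break_gap(self, pair_index: int):
        """(euclidean C->N distance, loop residue count) for adjacent pair i."""
        if self.n_sses < 2:
            raise GeometryError("model has no adjacent SSE pair")
        if not 0 <= pair_index < self.n_sses - 1:
            raise GeometryError("pair index out of range")
        up = self.sses[pair_index]
        down = self.sses[pair_index + 1]
        euclid = float(np.linalg.norm(down.coords[0, N] - up.coords[-1, C]))
        n_loop = down.first - up.last - 1
        return euclid, n_loop


def chain_break_gap(model: ProteinModel, pair_index: int):
    return model.chain_break_gap(pair_index)
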