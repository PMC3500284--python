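"""Composite 12-term energy over SSE-only protein models.

The total energy is a weighted sum of knowledge-based-style terms evaluated
on the rigid SSE arrangement only (loop residues are absent from the model;
solvation and secondary structure agreement also score the unfolded part).
Functional forms here are compact analytic stand-ins with the documented
constants; every constant is configurable.  Scores are in arbitrary score
units (su); lower is better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import CA, CB, ProteinModel
from .pool import PROB_FLOOR, SSPrediction

TERM_NAMES = (
    "aa_clash",
    "aa_pair_distance",
    "aa_solvation",
    "sse_pair_clash",
    "sse_packing",
    "strand_pairing",
    "loop_length",
    "loop_closure",
    "radius_of_gyration",
    "ss_agreement_method1",
    "ss_agreement_method2",
    "contact_order",
)

#: Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


class EnergyConfigError(ValueError):
    pass


from functools import lru_cache


@lru_cache(maxsize=8192)
def _kd_array(sequence: str) -> np.ndarray:
    arr = np.array([KYTE_DOOLITTLE[a] for a in sequence])
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True)
class EnergyConstants:
    """Constants of the individual terms (Angstrom / su)."""

    aa_clash_dmin: float = 3.0          # minimum CB-CB distance
    clash_kappa: float = 10.0           # su per square Angstrom of overlap
    sse_clash_dmin: dict = field(default_factory=lambda: {
        ("helix", "helix"): 7.0,
        ("helix", "strand"): 6.0,
        ("strand", "strand"): 4.0,
    })
    loop_length_rate: float = 2.5       # closable Angstrom per sqrt(loop residue)
    closure_per_residue: float = 2.56   # max span bridged per loop residue
    closure_offset: float = 2.0
    closure_penalty: float = 1000.0
    packing_cutoff: float = 12.0
    packing_ideal: dict = field(default_factory=lambda: {
        ("helix", "helix"): 9.5,
        ("helix", "strand"): 10.0,
    })
    packing_width: float = 3.0
    strand_pair_center: float = 4.75
    strand_pair_width: float = 1.0
    rg_coeff: float = 2.2               # expected Rg = coeff * N**exponent
    rg_exponent: float = 0.38
    co_target: float = 0.3              # preferred relative contact order
    co_scale: float = 0.15
    co_min_sep: int = 1
    co_cutoff: float = 8.0
    aa_pair_cutoff: float = 12.0
    aa_pair_min_sep: int = 5
    solvation_radius: float = 10.0
    solvation_ref_neighbors: float = 14.0  # preferred burial of a neutral residue
    solvation_sigma: float = 4.0          # width of the burial preference well


@dataclass(frozen=True)
class WeightSet:
    """Non-negative weight per energy term."""

    weights: dict

    def __post_init__(self):
        missing = set(TERM_NAMES) - set(self.weights)
        extra = set(self.weights) - set(TERM_NAMES)
        if missing or extra:
            raise EnergyConfigError(
                f"weight set must cover exactly the 12 terms; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        if any(w < 0 for w in self.weights.values()):
            raise EnergyConfigError("weights must be >= 0")

    @classmethod
    def default(cls) -> "WeightSet":
        return cls({name: 1.0 for name in TERM_NAMES})

    def __getitem__(self, name):
        return self.weights[name]


@dataclass
class EnergyBreakdown:
    raw: dict
    weighted: dict
    total: float

    @classmethod
    def from_raw(cls, raw: dict, w: WeightSet) -> "EnergyBreakdown":
        weighted = {k: raw[k] * w[k] for k in TERM_NAMES}
        return cls(raw=raw, weighted=weighted, total=float(sum(weighted.values())))


# ---------------------------------------------------------------------------
# Geometric helpers
# ---------------------------------------------------------------------------


def segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between segments p1-q1 and p2-q2."""
    # scalar arithmetic: called per SSE pair in the scoring hot loop
    p1x, p1y, p1z = float(p1[0]), float(p1[1]), float(p1[2])
    q1x, q1y, q1z = float(q1[0]), float(q1[1]), float(q1[2])
    p2x, p2y, p2z = float(p2[0]), float(p2[1]), float(p2[2])
    q2x, q2y, q2z = float(q2[0]), float(q2[1]), float(q2[2])
    d1x, d1y, d1z = q1x - p1x, q1y - p1y, q1z - p1z
    d2x, d2y, d2z = q2x - p2x, q2y - p2y, q2z - p2z
    rx, ry, rz = p1x - p2x, p1y - p2y, p1z - p2z
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz

    def clamp(v):
        return 0.0 if v < 0.0 else (1.0 if v > 1.0 else v)

    if a <= 1e-12 and e <= 1e-12:
        s = t = 0.0
    elif a <= 1e-12:
        s, t = 0.0, clamp(f / e)
    else:
        c = d1x * rx + d1y * ry + d1z * rz
        if e <= 1e-12:
            t, s = 0.0, clamp(-c / a)
        else:
            b = d1x * d2x + d1y * d2y + d1z * d2z
            denom = a * e - b * b
            s = clamp((b * f - c * e) / denom) if denom > 1e-12 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, clamp(-c / a)
            elif t > 1.0:
                t, s = 1.0, clamp((b - c) / a)
    dx = (p1x + s * d1x) - (p2x + t * d2x)
    dy = (p1y + s * d1y) - (p2y + t * d2y)
    dz = (p1z + s * d1z) - (p2z + t * d2z)
    return math.sqrt(dx * dx + dy * dy + dz * dz)


class _ModelGeometry:
    """Per-model arrays shared by all energy terms (computed once per score).

    Attributes: idx (1-based residue numbers), ca/cb coordinates, sse_ids,
    kd (hydropathy), d_cb (pairwise CB distances), sep (sequence
    separations), upper (strict upper-triangle mask), axis endpoints,
    pairwise axis segment distances and |cos| packing angles.
    """

    def __init__(self, model: ProteinModel):
        idx, cas, cbs, sse_ids, kds = [], [], [], [], []
        for si, sse in enumerate(model.sses):
            idx.append(np.arange(sse.first, sse.last + 1))
            cas.append(sse.coords[:, CA, :])
            cbs.append(sse.coords[:, CB, :])
            sse_ids.append(np.full(sse.n_res, si))
            kds.append(_kd_array(sse.sequence))
        self.idx = np.concatenate(idx)
        self.ca = np.concatenate(cas)
        self.cb = np.concatenate(cbs)
        self.sse_ids = np.concatenate(sse_ids)
        self.kd = np.concatenate(kds)
        self.d_cb = cdist(self.cb, self.cb)
        self.sep = np.abs(self.idx[:, None] - self.idx[None, :])
        self.upper = self.idx[:, None] < self.idx[None, :]
        n = model.n_sses
        ends = [s.axis_endpoints() for s in model.sses]
        dirs = [s.axis()[1] for s in model.sses]
        self.seg_dist = np.zeros((n, n))
        self.cos_angle = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = segment_distance(*ends[i], *ends[j])
                self.seg_dist[i, j] = self.seg_dist[j, i] = d
                c = abs(float(dirs[i] @ dirs[j]))
                self.cos_angle[i, j] = self.cos_angle[j, i] = c


def _gather(model: ProteinModel):
    """(indices, CA coords, CB coords, sse ids, kd values) over modeled residues."""
    g = _ModelGeometry(model)
    return g.idx, g.ca, g.cb, g.sse_ids, g.kd


def _pairing_distance(sse_a, sse_b) -> float:
    """Mean over the shorter strand's residues of the nearest CA distance."""
    ca_a = sse_a.coords[:, CA, :]
    ca_b = sse_b.coords[:, CA, :]
    if len(ca_a) > len(ca_b):
        ca_a, ca_b = ca_b, ca_a
    d = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=-1)
    return float(d.min(axis=1).mean())


def _pair_key(type_a: str, type_b: str):
    return tuple(sorted((type_a, type_b)))


# ---------------------------------------------------------------------------
# Term groups
# ---------------------------------------------------------------------------


def clash_terms(model: ProteinModel, c: EnergyConstants = EnergyConstants(),
                geom: _ModelGeometry | None = None):
    """(aa_clash, sse_pair_clash): quadratic penalties on sub-minimum distances."""
    if geom is None:
        geom = _ModelGeometry(model)
    aa = 0.0
    if model.n_sses >= 2:
        different = geom.sse_ids[:, None] != geom.sse_ids[None, :]
        overlap = np.maximum(0.0, c.aa_clash_dmin - geom.d_cb)
        aa = float(0.5 * (overlap[different] ** 2).sum() * c.clash_kappa)
    sse_clash = 0.0
    for i in range(model.n_sses):
        for j in range(i + 1, model.n_sses):
            a, b = model.sses[i], model.sses[j]
            dmin = c.sse_clash_dmin[_pair_key(a.ss_type, b.ss_type)]
            d = geom.seg_dist[i, j]
            if d < dmin:
                sse_clash += (dmin - d) ** 2 * c.clash_kappa
    return aa, float(sse_clash)


def loop_terms(model: ProteinModel, c: EnergyConstants = EnergyConstants()):
    """(loop_length, loop_closure) summed over adjacent SSE pairs."""
    loop_length = 0.0
    loop_closure = 0.0
    for i in range(model.n_sses - 1):
        euclid, n_loop = model.chain_break_gap(i)
        scale = np.sqrt(n_loop + 1.0)
        excess = euclid / scale - c.loop_length_rate
        if excess > 0:
            loop_length += excess**2
        if euclid > c.closure_per_residue * (n_loop + 1) + c.closure_offset:
            loop_closure += c.closure_penalty
    return float(loop_length), float(loop_closure)


def geometry_terms(model: ProteinModel, c: EnergyConstants = EnergyConstants(),
                   seq_length: int | None = None,
                   geom: _ModelGeometry | None = None):
    """(sse_packing, strand_pairing, radius_of_gyration, contact_order)."""
    if geom is None:
        geom = _ModelGeometry(model)
    packing = 0.0
    pairing = 0.0
    for i in range(model.n_sses):
        for j in range(i + 1, model.n_sses):
            a, b = model.sses[i], model.sses[j]
            key = _pair_key(a.ss_type, b.ss_type)
            if key == ("strand", "strand"):
                d = _pairing_distance(a, b)
                dev = (d - c.strand_pair_center) / c.strand_pair_width
                pairing -= max(0.0, 1.0 - dev**2)
                continue
            d = geom.seg_dist[i, j]
            if d < c.packing_cutoff:
                d0 = c.packing_ideal[key]
                well = max(0.0, 1.0 - ((d - d0) / c.packing_width) ** 2)
                packing -= well * (0.5 + 0.5 * geom.cos_angle[i, j])
    # radius of gyration vs. the expected compact-globule value
    rg_term = 0.0
    ca = geom.ca
    if len(ca) >= 2:
        rg = float(np.sqrt(((ca - ca.mean(0)) ** 2).sum(-1).mean()))
        rg_exp = c.rg_coeff * len(ca) ** c.rg_exponent
        rg_term = ((rg - rg_exp) / rg_exp) ** 2
    # contact order preference
    co_term = 0.0
    L = seq_length if seq_length is not None else len(model.sequence)
    if len(geom.idx) >= 2:
        contacts = (geom.sep >= c.co_min_sep) & (geom.d_cb < c.co_cutoff) & geom.upper
        if contacts.any():
            co = float(geom.sep[contacts].mean())
            rco = co / L
            co_term = ((rco - c.co_target) / c.co_scale) ** 2
    return float(packing), float(pairing), float(rg_term), float(co_term)


def profile_terms(model: ProteinModel, pred: SSPrediction | None,
                  c: EnergyConstants = EnergyConstants(),
                  geom: _ModelGeometry | None = None):
    """(aa_pair_distance, aa_solvation, ss_agreement_1, ss_agreement_2)."""
    if geom is None:
        geom = _ModelGeometry(model)
    aa_pair = 0.0
    solvation = 0.0
    if model.n_sses:
        kd = geom.kd
        # hydrophobicity-product attraction for distant-in-sequence contacts
        mask = (geom.sep >= c.aa_pair_min_sep) & (geom.d_cb < c.aa_pair_cutoff)
        mask &= geom.upper
        if mask.any():
            kk = kd[:, None] * kd[None, :]
            aa_pair = float(
                -(kk[mask] / 4.5**2 * (1.0 - geom.d_cb[mask] / c.aa_pair_cutoff)).sum()
            )
        # neighbor-count solvation: each residue prefers a burial level set
        # by its hydropathy (hydrophobics a crowded core, polars the
        # surface); deviations in either direction are penalized, so
        # exposed hydrophobics and over-buried polars both pay
        neighbors = ((geom.d_cb < c.solvation_radius).sum(axis=1) - 1).astype(float)
        preferred = np.clip(c.solvation_ref_neighbors + kd, 1.0, 30.0)
        solvation = float(
            (np.abs(kd) / 4.5 * ((neighbors - preferred) / c.solvation_sigma) ** 2
             - np.abs(kd) / 4.5).sum()
        )
    ss1 = ss2 = 0.0
    if pred is not None:
        # unmodeled residues are scored as coil (unfolded-part reference)
        state_idx = np.full(len(model.sequence), 2)
        for sse in model.sses:
            state_idx[sse.first - 1 : sse.last] = 0 if sse.ss_type == "helix" else 1
        rows = np.arange(len(state_idx))
        scores = []
        for probs in pred.methods.values():
            p = probs[rows, state_idx]
            scores.append(float(-np.log(np.maximum(p, PROB_FLOOR)).sum()))
        ss1 = scores[0]
        ss2 = scores[1] if len(scores) > 1 else 0.0
    return aa_pair, solvation, ss1, ss2


def score_model(
    model: ProteinModel,
    pred: SSPrediction | None,
    w: WeightSet | None = None,
    constants: EnergyConstants = EnergyConstants(),
) -> EnergyBreakdown:
    """Full 12-term breakdown of a model. Deterministic.

    The unfolded part of the protein (residues not in any SSE) contributes
    coil secondary structure agreement and a flat solvation reference of 0.
    """
    if w is None:
        w = WeightSet.default()
    needs_pred = (
        w["ss_agreement_method1"] > 0 or w["ss_agreement_method2"] > 0
    )
    if needs_pred and pred is None:
        raise EnergyConfigError(
            "secondary structure agreement weighted but no prediction given"
        )
    if model.n_sses < 1:
        raise EnergyConfigError("model must contain at least one SSE")
    geom = _ModelGeometry(model)
    aa_clash, sse_clash = clash_terms(model, constants, geom)
    loop_length, loop_closure = loop_terms(model, constants)
    packing, pairing, rg, co = geometry_terms(model, constants, geom=geom)
    aa_pair, solvation, ss1, ss2 = profile_terms(model, pred, constants, geom)
    raw = {
        "aa_clash": aa_clash,
        "aa_pair_distance": aa_pair,
        "aa_solvation": solvation,
        "sse_pair_clash": sse_clash,
        "sse_packing": packing,
        "strand_pairing": pairing,
        "loop_length": loop_length,
        "loop_closure": loop_closure,
        "radius_of_gyration": rg,
        "ss_agreement_method1": ss1,
        "ss_agreement_method2": ss2,
        "contact_order": co,
    }
    return EnergyBreakdown.from_raw(raw, w)
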