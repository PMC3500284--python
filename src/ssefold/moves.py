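"""Move registry for the conformational search.

Moves fall into six categories -- add, remove, swap, single-SSE, SSE-pair
and domain -- with helix/strand/sheet specializations, split between a
large-amplitude assembly stage and a small-amplitude refinement stage
(resize moves serve both).  A move either returns a new, valid model or
the ``SKIPPED`` marker when its structural prerequisites are absent; it
never mutates its input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    CA, MIN_SSE_LENGTH, NOMINAL_RISE, GeometryError, ProteinModel,
    RigidTransform, build_ideal_sse,
)
from .pool import SSEPool

#: sentinel outcome for a move whose prerequisites are absent
SKIPPED = "skipped"


class MoveError(ValueError):
    pass


@dataclass(frozen=True)
class MoveConfig:
    """Amplitudes and geometric thresholds of the move registry."""

    assembly_max_translation: float = 8.0   # Angstrom
    assembly_max_rotation: float = 90.0     # degrees
    refine_max_translation: float = 1.5
    refine_max_rotation: float = 15.0
    sheet_pairing_cutoff: float = 6.0       # strands closer than this pair up
    short_loop_max_residues: int = 7
    closure_per_residue: float = 2.56
    closure_offset: float = 2.0
    placement_distance: dict = field(default_factory=lambda: {
        ("helix", "helix"): 9.5,
        ("helix", "strand"): 10.0,
        ("strand", "strand"): 4.75,
    })
    #: relative category weights per stage
    assembly_weights: dict = field(default_factory=lambda: {
        "add": 0.25, "remove": 0.05, "swap": 0.10,
        "single_sse": 0.30, "sse_pair": 0.15, "domain": 0.15,
    })
    refinement_weights: dict = field(default_factory=lambda: {
        "single_sse": 0.50, "sse_pair": 0.25, "domain": 0.15, "resize": 0.10,
    })


@dataclass(frozen=True)
class Move:
    name: str
    category: str       # add | remove | swap | single_sse | sse_pair | domain
    stage: str          # assembly | refinement | both
    amplitude: str      # large | small
    fn: object
    needs_strands: bool = False
    needs_helices: bool = False
    weight: float = 0.0


@dataclass
class MoveSet:
    moves: list
    probabilities: np.ndarray
    stage: str

    def __post_init__(self):
        self._cumulative = np.cumsum(self.probabilities)

    def sample(self, rng) -> Move:
        i = int(np.searchsorted(self._cumulative, rng.random(), side="right"))
        return self.moves[min(i, len(self.moves) - 1)]


# ---------------------------------------------------------------------------
# Random-geometry helpers
# ---------------------------------------------------------------------------


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_rotation_about_center(rng, max_deg: float, center) -> RigidTransform:
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    return RigidTransform.from_rotation_about(_random_unit(rng), angle, center)


def _segment(model: ProteinModel, first: int, last: int) -> str:
    return model.sequence[first - 1 : last]


def _pair_key(a, b):
    return tuple(sorted((a, b)))


def _try_model(model: ProteinModel, sses) -> ProteinModel | None:
    try:
        return model.replace_sses(sses)
    except GeometryError:
        return None


def _free_pool_entries(model: ProteinModel, pool: SSEPool):
    return [e for e in pool if not model.overlaps(e.first, e.last)]


def _strand_indices(model: ProteinModel):
    return [i for i, s in enumerate(model.sses) if s.ss_type == "strand"]


def _pairing_dist(a, b) -> float:
    ca_a, ca_b = a.coords[:, CA, :], b.coords[:, CA, :]
    if len(ca_a) > len(ca_b):
        ca_a, ca_b = ca_b, ca_a
    d = np.linalg.norm(ca_a[:, None] - ca_b[None], axis=-1)
    return float(d.min(axis=1).mean())


def detect_sheets(model: ProteinModel, cutoff: float = 6.0):
    """Connected components of strands with pairing distance < cutoff.

    Returns a list of sheets, each a list of SSE indices (>= 2 strands).
    """
    strands = _strand_indices(model)
    parent = {i: i for i in strands}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(strands)):
        for b in range(a + 1, len(strands)):
            i, j = strands[a], strands[b]
            if _pairing_dist(model.sses[i], model.sses[j]) < cutoff:
                parent[find(i)] = find(j)
    sheets = {}
    for i in strands:
        sheets.setdefault(find(i), []).append(i)
    return [sorted(v) for v in sheets.values() if len(v) >= 2]


def _place_at(entry, model, center, direction, rng) -> "SSE":
    """Build entry's ideal SSE and place its axis at center along direction,
    with a random spin about the axis."""
    sse = build_ideal_sse(
        _segment(model, entry.first, entry.last), entry.first, entry.last,
        entry.ss_type,
    )
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(z, direction)
    nrm = np.linalg.norm(axis)
    if nrm < 1e-9:
        align = RigidTransform.identity() if direction[2] > 0 else \
            RigidTransform.from_rotation_about([1.0, 0, 0], np.pi)
    else:
        angle = float(np.arccos(np.clip(z @ direction, -1.0, 1.0)))
        align = RigidTransform.from_rotation_about(axis / nrm, angle)
    spin = RigidTransform.from_rotation_about(z, rng.uniform(0, 2 * np.pi))
    t = RigidTransform.from_translation(center).compose(align.compose(spin))
    return sse.transformed(t)


# ---------------------------------------------------------------------------
# Add moves
# ---------------------------------------------------------------------------


def add_sse_random(model, pool, rng, cfg):
    free = _free_pool_entries(model, pool)
    if not free:
        return SKIPPED
    entry = free[int(rng.integers(len(free)))]
    if model.n_sses == 0:
        center = np.zeros(3)
    else:
        anchor = model.sses[int(rng.integers(model.n_sses))]
        center = anchor.axis()[0] + _random_unit(rng) * rng.uniform(6.0, 14.0)
    placed = _place_at(entry, model, center, _random_unit(rng), rng)
    return _try_model(model, model.sses + [placed]) or SKIPPED


def add_sse_next_to_sse(model, pool, rng, cfg):
    free = _free_pool_entries(model, pool)
    if not free or model.n_sses == 0:
        return SKIPPED
    entry = free[int(rng.integers(len(free)))]
    anchor = model.sses[int(rng.integers(model.n_sses))]
    center_a, dir_a, _ = anchor.axis()
    d0 = cfg.placement_distance[_pair_key(anchor.ss_type, entry.ss_type)]
    # random azimuth perpendicular to the anchor axis, ideal packing distance
    perp = np.cross(dir_a, _random_unit(rng))
    nrm = np.linalg.norm(perp)
    if nrm < 1e-9:
        return SKIPPED
    perp /= nrm
    direction = dir_a if rng.random() < 0.5 else -dir_a
    placed = _place_at(entry, model, center_a + perp * d0, direction, rng)
    return _try_model(model, model.sses + [placed]) or SKIPPED


def add_sse_short_loop(model, pool, rng, cfg):
    """Add a pool SSE sequence-adjacent to a model SSE within closable reach."""
    if model.n_sses == 0:
        return SKIPPED
    candidates = []
    for entry in _free_pool_entries(model, pool):
        for sse in model.sses:
            if entry.first > sse.last:
                n_loop = entry.first - sse.last - 1
            elif entry.last < sse.first:
                n_loop = sse.first - entry.last - 1
            else:
                continue
            if 0 <= n_loop <= cfg.short_loop_max_residues:
                candidates.append((entry, sse, n_loop))
    if not candidates:
        return SKIPPED
    entry, anchor, n_loop = candidates[int(rng.integers(len(candidates)))]
    limit = cfg.closure_per_residue * (n_loop + 1) + cfg.closure_offset
    downstream = entry.first > anchor.last
    from .geometry import C as C_AT, N as N_AT
    anchor_pt = anchor.coords[-1, C_AT] if downstream else anchor.coords[0, N_AT]
    for _ in range(30):
        center = anchor_pt + _random_unit(rng) * rng.uniform(2.0, max(3.0, 0.8 * limit))
        placed = _place_at(entry, model, center, _random_unit(rng), rng)
        end_pt = placed.coords[0, N_AT] if downstream else placed.coords[-1, C_AT]
        if float(np.linalg.norm(end_pt - anchor_pt)) <= limit:
            new = _try_model(model, model.sses + [placed])
            if new is not None:
                return new
    return SKIPPED


def add_strand_next_to_sheet(model, pool, rng, cfg):
    free = [e for e in _free_pool_entries(model, pool) if e.ss_type == "strand"]
    strands = _strand_indices(model)
    if not free or not strands:
        return SKIPPED
    entry = free[int(rng.integers(len(free)))]
    sheets = detect_sheets(model, cfg.sheet_pairing_cutoff)
    if sheets:
        sheet = sheets[int(rng.integers(len(sheets)))]
        # extend at a randomly chosen edge strand
        edge = model.sses[sheet[0] if rng.random() < 0.5 else sheet[-1]]
        others = [model.sses[i] for i in sheet if model.sses[i] is not edge]
        away = edge.axis()[0] - np.mean([o.axis()[0] for o in others], axis=0)
    else:
        edge = model.sses[strands[int(rng.integers(len(strands)))]]
        away = _random_unit(rng)
    center_e, dir_e, _ = edge.axis()
    perp = away - (away @ dir_e) * dir_e
    nrm = np.linalg.norm(perp)
    if nrm < 1e-9:
        perp = np.cross(dir_e, _random_unit(rng))
        nrm = np.linalg.norm(perp)
        if nrm < 1e-9:
            return SKIPPED
    perp /= nrm
    d0 = cfg.placement_distance[("strand", "strand")]
    direction = dir_e if rng.random() < 0.5 else -dir_e
    placed = _place_at(entry, model, center_e + perp * d0, direction, rng)
    return _try_model(model, model.sses + [placed]) or SKIPPED


# ---------------------------------------------------------------------------
# Remove / swap moves
# ---------------------------------------------------------------------------


def remove_random(model, pool, rng, cfg):
    if model.n_sses < 2:  # never empty the model
        return SKIPPED
    return model.without(int(rng.integers(model.n_sses)))


def remove_unpaired_strand(model, pool, rng, cfg):
    if model.n_sses < 2:
        return SKIPPED
    strands = _strand_indices(model)
    unpaired = [
        i for i in strands
        if all(
            _pairing_dist(model.sses[i], model.sses[j]) >= cfg.sheet_pairing_cutoff
            for j in strands if j != i
        )
    ]
    if not unpaired:
        return SKIPPED
    return model.without(unpaired[int(rng.integers(len(unpaired)))])


def _exchange_frames(model, i, j):
    a, b = model.sses[i], model.sses[j]
    to_b = b.body_frame.compose(a.body_frame.inverse())
    to_a = a.body_frame.compose(b.body_frame.inverse())
    new = list(model.sses)
    new[i] = a.transformed(to_b)
    new[j] = b.transformed(to_a)
    return _try_model(model, new)


def swap_sses(model, pool, rng, cfg):
    """Exchange the spatial placements of two same-type SSEs."""
    by_type = {}
    for i, s in enumerate(model.sses):
        by_type.setdefault(s.ss_type, []).append(i)
    pairs = [t for t, idxs in by_type.items() if len(idxs) >= 2]
    if not pairs:
        return SKIPPED
    idxs = by_type[pairs[int(rng.integers(len(pairs)))]]
    i, j = rng.choice(idxs, size=2, replace=False)
    return _exchange_frames(model, int(i), int(j)) or SKIPPED


def swap_sse_with_pool(model, pool, rng, cfg):
    """Replace a model SSE by an overlapping pool alternative, same placement."""
    options = []
    for i, s in enumerate(model.sses):
        for e in pool:
            if (e.first, e.last, e.ss_type) == (s.first, s.last, s.ss_type):
                continue
            if e.last < s.first or e.first > s.last:
                continue
            others = [o for o in model.sses if o is not s]
            if any(not (e.last < o.first or e.first > o.last) for o in others):
                continue
            options.append((i, e))
    if not options:
        return SKIPPED
    i, e = options[int(rng.integers(len(options)))]
    s = model.sses[i]
    repl = build_ideal_sse(
        _segment(model, e.first, e.last), e.first, e.last, e.ss_type
    ).transformed(s.body_frame)
    new = list(model.sses)
    new[i] = repl
    return _try_model(model, new) or SKIPPED


# ---------------------------------------------------------------------------
# Single-SSE moves
# ---------------------------------------------------------------------------


def _single_sse_transform(model, rng, make_transform):
    if model.n_sses == 0:
        return SKIPPED
    i = int(rng.integers(model.n_sses))
    sse = model.sses[i]
    new = list(model.sses)
    new[i] = sse.transformed(make_transform(sse))
    return _try_model(model, new) or SKIPPED


def _translate_move(max_amp):
    def fn(model, pool, rng, cfg):
        amp = getattr(cfg, max_amp)
        return _single_sse_transform(
            model, rng,
            lambda s: RigidTransform.from_translation(
                _random_unit(rng) * rng.uniform(0, amp)
            ),
        )
    return fn


def _rotate_move(max_amp):
    def fn(model, pool, rng, cfg):
        amp = getattr(cfg, max_amp)
        return _single_sse_transform(
            model, rng,
            lambda s: _random_rotation_about_center(rng, amp, s.axis()[0]),
        )
    return fn


def _transform_move(max_trans, max_rot):
    def fn(model, pool, rng, cfg):
        t_amp, r_amp = getattr(cfg, max_trans), getattr(cfg, max_rot)
        def make(s):
            rot = _random_rotation_about_center(rng, r_amp, s.axis()[0])
            tra = RigidTransform.from_translation(
                _random_unit(rng) * rng.uniform(0, t_amp)
            )
            return tra.compose(rot)
        return _single_sse_transform(model, rng, make)
    return fn


def strand_translate_z_small(model, pool, rng, cfg):
    """Shift one strand along its own axis (registry shift)."""
    strands = _strand_indices(model)
    if not strands:
        return SKIPPED
    i = strands[int(rng.integers(len(strands)))]
    sse = model.sses[i]
    shift = sse.axis()[1] * rng.uniform(-NOMINAL_RISE["strand"], NOMINAL_RISE["strand"])
    new = list(model.sses)
    new[i] = sse.transformed(RigidTransform.from_translation(shift))
    return _try_model(model, new) or SKIPPED


def _resize(model, pool, rng, cfg, terminus: str):
    if model.n_sses == 0:
        return SKIPPED
    order = rng.permutation(model.n_sses)
    for i in order:
        i = int(i)
        sse = model.sses[i]
        grow = bool(rng.random() < 0.5)
        min_len = MIN_SSE_LENGTH[sse.ss_type]
        if terminus == "n":
            first, last = (sse.first - 1, sse.last) if grow else (sse.first + 1, sse.last)
        else:
            first, last = (sse.first, sse.last + 1) if grow else (sse.first, sse.last - 1)
        if first < 1 or last > len(model.sequence) or last - first + 1 < min_len:
            continue
        others = [o for o in model.sses if o is not sse]
        if any(not (last < o.first or first > o.last) for o in others):
            continue
        new = list(model.sses)
        new[i] = sse.with_bounds(first, last, _segment(model, first, last))
        result = _try_model(model, new)
        if result is not None:
            return result
    return SKIPPED


def sse_resize_nterm(model, pool, rng, cfg):
    return _resize(model, pool, rng, cfg, "n")


def sse_resize_cterm(model, pool, rng, cfg):
    return _resize(model, pool, rng, cfg, "c")


def sse_split(model, pool, rng, cfg):
    """Divide one SSE into two pieces (1-residue coil gap), same placement."""
    options = []
    for i, s in enumerate(model.sses):
        min_len = MIN_SSE_LENGTH[s.ss_type]
        for cut in range(s.first + min_len - 1, s.last - min_len):
            # pieces [first, cut] and [cut+2, last]
            if cut - s.first + 1 >= min_len and s.last - cut - 1 >= min_len:
                options.append((i, cut))
    if not options:
        return SKIPPED
    i, cut = options[int(rng.integers(len(options)))]
    s = model.sses[i]
    left = s.with_bounds(s.first, cut, _segment(model, s.first, cut))
    right = s.with_bounds(cut + 2, s.last, _segment(model, cut + 2, s.last))
    new = [o for o in model.sses if o is not s] + [left, right]
    return _try_model(model, new) or SKIPPED


# ---------------------------------------------------------------------------
# SSE-pair moves
# ---------------------------------------------------------------------------


def _pair_translate(max_amp):
    def fn(model, pool, rng, cfg):
        if model.n_sses < 2:
            return SKIPPED
        amp = getattr(cfg, max_amp)
        i, j = rng.choice(model.n_sses, size=2, replace=False)
        shift = RigidTransform.from_translation(_random_unit(rng) * rng.uniform(0, amp))
        new = list(model.sses)
        for k in (int(i), int(j)):
            new[k] = new[k].transformed(shift)
        return _try_model(model, new) or SKIPPED
    return fn


def _pair_rotate_hinge(max_amp):
    def fn(model, pool, rng, cfg):
        if model.n_sses < 2:
            return SKIPPED
        amp = getattr(cfg, max_amp)
        i, j = rng.choice(model.n_sses, size=2, replace=False)
        hinge = model.sses[int(i)]
        center, direction, _ = hinge.axis()
        angle = np.deg2rad(rng.uniform(-amp, amp))
        rot = RigidTransform.from_rotation_about(direction, angle, center)
        new = list(model.sses)
        new[int(j)] = new[int(j)].transformed(rot)
        return _try_model(model, new) or SKIPPED
    return fn


def sheet_pair_strands(model, pool, rng, cfg):
    """Bring an unpaired strand next to another strand at pairing distance."""
    strands = _strand_indices(model)
    if len(strands) < 2:
        return SKIPPED
    unpaired = [
        i for i in strands
        if all(
            _pairing_dist(model.sses[i], model.sses[j]) >= cfg.sheet_pairing_cutoff
            for j in strands if j != i
        )
    ]
    if not unpaired:
        return SKIPPED
    i = unpaired[int(rng.integers(len(unpaired)))]
    targets = [j for j in strands if j != i]
    j = targets[int(rng.integers(len(targets)))]
    target = model.sses[j]
    center_t, dir_t, _ = target.axis()
    perp = np.cross(dir_t, _random_unit(rng))
    nrm = np.linalg.norm(perp)
    if nrm < 1e-9:
        return SKIPPED
    perp /= nrm
    d0 = cfg.placement_distance[("strand", "strand")]
    moving = model.sses[i]
    direction = dir_t if rng.random() < 0.5 else -dir_t
    goal_center = center_t + perp * d0
    center_m, dir_m, _ = moving.axis()
    # rotate moving strand to align with the target direction, then translate
    axis = np.cross(dir_m, direction)
    nrm2 = np.linalg.norm(axis)
    if nrm2 < 1e-9:
        rot = RigidTransform.identity()
    else:
        ang = float(np.arccos(np.clip(dir_m @ direction, -1, 1)))
        rot = RigidTransform.from_rotation_about(axis / nrm2, ang, center_m)
    shift = RigidTransform.from_translation(goal_center - rot.apply(center_m))
    new = list(model.sses)
    new[i] = moving.transformed(shift.compose(rot))
    return _try_model(model, new) or SKIPPED


# ---------------------------------------------------------------------------
# Domain moves
# ---------------------------------------------------------------------------


def _sheet_of(model, rng, cfg):
    sheets = detect_sheets(model, cfg.sheet_pairing_cutoff)
    if not sheets:
        return None
    return sheets[int(rng.integers(len(sheets)))]


def domain_shuffle_sheet(model, pool, rng, cfg):
    sheet = _sheet_of(model, rng, cfg)
    if sheet is None or len(sheet) < 2:
        return SKIPPED
    i, j = rng.choice(sheet, size=2, replace=False)
    return _exchange_frames(model, int(i), int(j)) or SKIPPED


def domain_flip_sheet(model, pool, rng, cfg):
    """Rigidly flip a whole sheet 180 degrees about its mean strand axis."""
    sheet = _sheet_of(model, rng, cfg)
    if sheet is None:
        return SKIPPED
    axes = [model.sses[i].axis() for i in sheet]
    ref = axes[0][1]
    mean_dir = np.sum(
        [d if d @ ref >= 0 else -d for _, d, _ in axes], axis=0
    )
    mean_dir /= np.linalg.norm(mean_dir)
    centroid = np.mean([c for c, _, _ in axes], axis=0)
    flip = RigidTransform.from_rotation_about(mean_dir, np.pi, centroid)
    new = list(model.sses)
    for i in sheet:
        new[i] = new[i].transformed(flip)
    return _try_model(model, new) or SKIPPED


def _domain_translate(max_amp):
    def fn(model, pool, rng, cfg):
        if model.n_sses < 2:
            return SKIPPED
        amp = getattr(cfg, max_amp)
        k = int(rng.integers(2, model.n_sses + 1))
        members = rng.choice(model.n_sses, size=k, replace=False)
        shift = RigidTransform.from_translation(_random_unit(rng) * rng.uniform(0, amp))
        new = list(model.sses)
        for i in members:
            new[int(i)] = new[int(i)].transformed(shift)
        return _try_model(model, new) or SKIPPED
    return fn


def sheet_divide(model, pool, rng, cfg):
    """Break a large sheet in two and offset one half (sandwich creation)."""
    sheets = [s for s in detect_sheets(model, cfg.sheet_pairing_cutoff) if len(s) >= 4]
    if not sheets:
        return SKIPPED
    sheet = sheets[int(rng.integers(len(sheets)))]
    half = sheet[len(sheet) // 2:]
    axes = [model.sses[i].axis() for i in sheet]
    ref = axes[0][1]
    mean_dir = np.sum([d if d @ ref >= 0 else -d for _, d, _ in axes], axis=0)
    mean_dir /= np.linalg.norm(mean_dir)
    perp = np.cross(mean_dir, _random_unit(rng))
    nrm = np.linalg.norm(perp)
    if nrm < 1e-9:
        return SKIPPED
    shift = RigidTransform.from_translation(perp / nrm * 10.0)
    new = list(model.sses)
    for i in half:
        new[i] = new[i].transformed(shift)
    return _try_model(model, new) or SKIPPED


# ---------------------------------------------------------------------------
# Registry and move-set construction
# ---------------------------------------------------------------------------

REGISTRY = [
    Move("add_sse_random", "add", "assembly", "large", add_sse_random),
    Move("add_sse_next_to_sse", "add", "assembly", "large", add_sse_next_to_sse),
    Move("add_sse_short_loop", "add", "assembly", "large", add_sse_short_loop),
    Move("add_strand_next_to_sheet", "add", "assembly", "large",
         add_strand_next_to_sheet, needs_strands=True),
    Move("remove_random", "remove", "assembly", "large", remove_random),
    Move("remove_unpaired_strand", "remove", "assembly", "large",
         remove_unpaired_strand, needs_strands=True),
    Move("swap_sses", "swap", "assembly", "large", swap_sses),
    Move("swap_sse_with_pool", "swap", "assembly", "large", swap_sse_with_pool),
    Move("sse_translate_large", "single_sse", "assembly", "large",
         _translate_move("assembly_max_translation")),
    Move("sse_rotate_large", "single_sse", "assembly", "large",
         _rotate_move("assembly_max_rotation")),
    Move("sse_transform_large", "single_sse", "assembly", "large",
         _transform_move("assembly_max_translation", "assembly_max_rotation")),
    Move("sse_split", "single_sse", "assembly", "large", sse_split),
    Move("sse_translate_small", "single_sse", "refinement", "small",
         _translate_move("refine_max_translation")),
    Move("sse_rotate_small", "single_sse", "refinement", "small",
         _rotate_move("refine_max_rotation")),
    Move("sse_transform_small", "single_sse", "refinement", "small",
         _transform_move("refine_max_translation", "refine_max_rotation")),
    Move("strand_translate_z_small", "single_sse", "refinement", "small",
         strand_translate_z_small, needs_strands=True),
    Move("sse_resize_nterm", "single_sse", "both", "small", sse_resize_nterm),
    Move("sse_resize_cterm", "single_sse", "both", "small", sse_resize_cterm),
    Move("sse_pair_translate_large", "sse_pair", "assembly", "large",
         _pair_translate("assembly_max_translation")),
    Move("sse_pair_rotate_hinge_large", "sse_pair", "assembly", "large",
         _pair_rotate_hinge("assembly_max_rotation")),
    Move("sheet_pair_strands", "sse_pair", "assembly", "large",
         sheet_pair_strands, needs_strands=True),
    Move("sse_pair_translate_small", "sse_pair", "refinement", "small",
         _pair_translate("refine_max_translation")),
    Move("sse_pair_rotate_hinge_small", "sse_pair", "refinement", "small",
         _pair_rotate_hinge("refine_max_rotation")),
    Move("domain_shuffle_sheet", "domain", "assembly", "large",
         domain_shuffle_sheet, needs_strands=True),
    Move("domain_flip_sheet", "domain", "assembly", "large",
         domain_flip_sheet, needs_strands=True),
    Move("sheet_divide", "domain", "assembly", "large",
         sheet_divide, needs_strands=True),
    Move("domain_translate_large", "domain", "assembly", "large",
         _domain_translate("assembly_max_translation")),
    Move("domain_translate_small", "domain", "refinement", "small",
         _domain_translate("refine_max_translation")),
]

MOVE_NAMES = tuple(m.name for m in REGISTRY)


def build_move_set(pool: SSEPool, stage: str, cfg: MoveConfig = MoveConfig()) -> MoveSet:
    """Stage move set with pool-dependent weights.

    Strand/sheet moves get weight 0 when the pool has no strands (and
    helix-requiring moves likewise); category weights are split evenly over
    the remaining moves of each category and renormalized.
    """
    if len(pool) == 0:
        raise MoveError("empty pool")
    if stage not in ("assembly", "refinement"):
        raise MoveError(f"unknown stage {stage!r}")
    has_strands = pool.has_type("strand")
    has_helices = pool.has_type("helix")
    cat_weights = (
        cfg.assembly_weights if stage == "assembly" else cfg.refinement_weights
    )
    resize_bucket = "resize" in cat_weights

    def bucket(move: Move) -> str:
        if resize_bucket and move.name.startswith("sse_resize"):
            return "resize"
        return move.category

    selected = []
    for move in REGISTRY:
        if move.stage not in (stage, "both"):
            continue
        w = cat_weights.get(bucket(move), 0.0)
        if move.needs_strands and not has_strands:
            w = 0.0
        if move.needs_helices and not has_helices:
            w = 0.0
        selected.append(replace(move, weight=w))
    # split each category weight over its members
    by_bucket = {}
    for m in selected:
        by_bucket.setdefault(bucket(m), []).append(m)
    probs = []
    for m in selected:
        live = [x for x in by_bucket[bucket(m)] if x.weight > 0]
        probs.append(m.weight / len(live) if (live and m.weight > 0) else 0.0)
    probs = np.asarray(probs, dtype=float)
    total = probs.sum()
    if total <= 0:
        raise MoveError("no applicable moves for this pool/stage")
    return MoveSet(moves=selected, probabilities=probs / total, stage=stage)


def propose(move: Move, model: ProteinModel, pool: SSEPool, rng,
            cfg: MoveConfig = MoveConfig()):
    """Apply a move; returns a new model or the SKIPPED marker."""
    result = move.fn(model, pool, rng, cfg)
    return result
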