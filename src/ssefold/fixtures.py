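"""Synthetic toy proteins: designed SSE arrangements with perfect
predictions and native pools.

A toy topology places idealized SSEs at explicit offsets/orientations,
derives a closable loop layout, designs a sequence with a hydrophobic
period matching each SSE type, and emits everything the pipeline consumes:
the native SSE-only model, a complete loop-built structure, a "perfect"
3-state prediction (p = 0.95 on the true state), the native pool and the
per-residue native assignment.  These fixtures emulate compact single-chain
globular arrangements at desk scale; they are not PDB-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import LoopSettings
from .geometry import (
    GeometryError, ProteinModel, RigidTransform, build_ideal_sse,
)
from .loops import BuiltStructure, RamachandranTable, build_all_loops
from .pool import PoolEntry, SSEPool, SSPrediction


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class ToySSE:
    ss_type: str
    length: int
    offset: tuple        # (x, y, z) of the axis center, Angstrom
    flip: bool = False   # antiparallel: axis along -z instead of +z
    spin: float | None = None  # rotation about own axis (rad); None = designed


@dataclass(frozen=True)
class ToyTopologySpec:
    """A toy protein: SSEs at fixed placements joined by closable loops."""

    sses: tuple
    loop_lengths: tuple         # len(sses) - 1 entries
    nterm_tail: int = 1
    cterm_tail: int = 1
    closure_per_residue: float = 2.56
    closure_offset: float = 2.0

    def __post_init__(self):
        if len(self.loop_lengths) != len(self.sses) - 1:
            raise FixtureError("need exactly one loop length per SSE junction")

    @classmethod
    def three_helix_bundle(cls, helix_length: int = 16, spacing: float = 9.5,
                           loop_length: int = 5) -> "ToyTopologySpec":
        """Antiparallel three-helix bundle (the standard toy)."""
        return cls(
            sses=(
                ToySSE("helix", helix_length, (0.0, 0.0, 0.0), False),
                ToySSE("helix", helix_length, (spacing, 0.0, 0.0), True),
                ToySSE("helix", helix_length, (spacing / 2, spacing * 0.87, 0.0), False),
            ),
            loop_lengths=(loop_length, loop_length),
        )

    @classmethod
    def strand_pair(cls, strand_length: int = 6, spacing: float = 4.75,
                    loop_length: int = 3) -> "ToyTopologySpec":
        return cls(
            sses=(
                ToySSE("strand", strand_length, (0.0, 0.0, 0.0), False),
                ToySSE("strand", strand_length, (spacing, 0.0, 0.0), True),
            ),
            loop_lengths=(loop_length,),
        )


def _optimize_spins(model: ProteinModel, free_flags, n_angles: int = 24,
                    sweeps: int = 2) -> ProteinModel:
    """Greedy per-SSE spin search minimizing the sequence-dependent energy."""
    from .energy import profile_terms

    def seq_score(m):
        aa_pair, solvation, _, _ = profile_terms(m, None)
        return aa_pair + solvation

    best_score = seq_score(model)
    for _ in range(sweeps):
        for i, free in enumerate(free_flags):
            if not free:
                continue
            for k in range(1, n_angles):
                angle = 2.0 * np.pi * k / n_angles
                sse = model.sses[i]
                center, direction, _ = sse.axis()
                rot = RigidTransform.from_rotation_about(direction, angle, center)
                trial_sses = list(model.sses)
                trial_sses[i] = sse.transformed(rot)
                trial = model.replace_sses(trial_sses)
                s = seq_score(trial)
                if s < best_score:
                    best_score = s
                    model = trial
    return model


#: residue alphabets used by the sequence designer
_HYDROPHOBIC = "LVIF"
_POLAR = "SETKQN"
_LOOP = "GSDG"


def _design_sequence(spec: ToyTopologySpec, rng) -> tuple:
    """Sequence plus (first, last) bounds per SSE.

    SSE residues alternate hydrophobic/polar with the type's natural period
    (3.6 for helices via the i, i+3/i+4 pattern approximated by period 7/2;
    every other residue for strands); loops are flexible glycine/serine.
    """
    seq = []
    bounds = []
    pos = 0
    seq.extend(rng.choice(list(_LOOP), size=spec.nterm_tail))
    pos += spec.nterm_tail
    for k, toy in enumerate(spec.sses):
        first = pos + 1
        for i in range(toy.length):
            if toy.ss_type == "helix":
                core = (i % 7) in (0, 3, 4)   # heptad a/d-like positions
            else:
                core = i % 2 == 0
            alphabet = _HYDROPHOBIC if core else _POLAR
            seq.append(str(rng.choice(list(alphabet))))
            pos += 1
        bounds.append((first, pos))
        if k < len(spec.sses) - 1:
            seq.extend(rng.choice(list(_LOOP), size=spec.loop_lengths[k]))
            pos += spec.loop_lengths[k]
    seq.extend(rng.choice(list(_LOOP), size=spec.cterm_tail))
    return "".join(seq), bounds


@dataclass
class ToyProtein:
    sequence: str
    native: ProteinModel          # SSE-only native model
    complete: BuiltStructure      # loop-built native structure
    prediction: SSPrediction      # perfect 3-state prediction (two methods)
    pool: SSEPool                 # native SSE bounds
    native_labels: np.ndarray     # per-residue H/E/C
    native_sses: list = field(default_factory=list)


def generate_toy_protein(spec: ToyTopologySpec, seed: int = 0,
                         loop_settings: LoopSettings = LoopSettings()) -> ToyProtein:
    """Deterministic toy protein for a topology spec."""
    rng = np.random.default_rng(seed)
    sequence, bounds = _design_sequence(spec, rng)
    sses = []
    for toy, (first, last) in zip(spec.sses, bounds):
        sse = build_ideal_sse(sequence[first - 1 : last], first, last, toy.ss_type)
        t = RigidTransform.from_translation(np.asarray(toy.offset, dtype=float))
        if toy.flip:
            t = t.compose(RigidTransform.from_rotation_about([1.0, 0.0, 0.0], np.pi))
        if toy.spin is not None:
            t = t.compose(RigidTransform.from_rotation_about([0.0, 0.0, 1.0], toy.spin))
        sses.append(sse.transformed(t))
    try:
        native = ProteinModel(sequence, sses, provenance="toy-native")
    except GeometryError as exc:
        raise FixtureError(f"invalid toy placement: {exc}") from exc
    # design step: spin each SSE about its own axis (where the spec leaves
    # the spin free) so hydrophobic faces point into the core -- the native
    # fixture should sit near the optimum of the sequence-dependent terms
    native = _optimize_spins(
        native, [toy.spin is None for toy in spec.sses]
    )
    sses = native.sses
    # closability check
    for i in range(native.n_sses - 1):
        euclid, n_loop = native.chain_break_gap(i)
        limit = spec.closure_per_residue * (n_loop + 1) + spec.closure_offset
        if euclid > limit:
            raise FixtureError(
                f"junction {i}: gap {euclid:.1f} A over {n_loop} residues is "
                f"not closable (limit {limit:.1f} A)"
            )
    labels = np.full(len(sequence), "C")
    entries = []
    for toy, (first, last) in zip(spec.sses, bounds):
        labels[first - 1 : last] = "H" if toy.ss_type == "helix" else "E"
        entries.append(PoolEntry(toy.ss_type, first, last))
    probs = np.full((len(sequence), 3), 0.025)
    state_col = {"H": 0, "E": 1, "C": 2}
    for i, s in enumerate(labels):
        probs[i, state_col[s]] = 0.95
    prediction = SSPrediction({"psipred": probs.copy(), "jufo": probs.copy()})
    pool = SSEPool(entries, source="toy-native")
    complete = build_all_loops(
        native, np.random.default_rng(seed + 1),
        RamachandranTable.default(), loop_settings,
    )
    return ToyProtein(
        sequence=sequence,
        native=native,
        complete=complete,
        prediction=prediction,
        pool=pool,
        native_labels=labels,
        native_sses=list(entries),
    )
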