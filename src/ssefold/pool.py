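"""SSE pool construction from 3-state secondary structure predictions.

The pool is the set of candidate helices/strands the assembly stage draws
from.  It is built from per-residue (helix, strand, coil) probabilities of
two prediction methods, thresholded and length-filtered, then optionally
refined by a greedy Monte Carlo minimization of an agreement score.  Pools
are evaluated against native assignments with Q3, %found and shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .geometry import MIN_SSE_LENGTH

STATES = ("H", "E", "C")  # helix, strand, coil; column order of prob arrays
PROB_FLOOR = 1e-4


class PoolError(ValueError):
    pass


class PoolEntry(NamedTuple):
    ss_type: str  # "helix" | "strand"
    first: int    # 1-based inclusive
    last: int


_STATE_OF_TYPE = {"helix": "H", "strand": "E"}
_TYPE_OF_STATE = {"H": "helix", "E": "strand"}


@dataclass
class SSPrediction:
    """Per-residue 3-state probabilities for up to two prediction methods.

    Each value is an (L, 3) array with columns (p_helix, p_strand, p_coil)
    summing to 1 per residue.
    """

    methods: dict = field(default_factory=dict)

    def __post_init__(self):
        lengths = set()
        for name, probs in self.methods.items():
            probs = np.asarray(probs, dtype=float)
            if probs.ndim != 2 or probs.shape[1] != 3:
                raise PoolError(f"method {name!r}: expected (L, 3) probabilities")
            if np.any(probs < 0) or np.any(probs > 1):
                raise PoolError(f"method {name!r}: probabilities outside [0, 1]")
            sums = probs.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise PoolError(f"method {name!r}: probabilities do not sum to 1")
            self.methods[name] = probs
            lengths.add(len(probs))
        if len(lengths) > 1:
            raise PoolError("prediction methods disagree on sequence length")

    @property
    def length(self) -> int:
        return len(next(iter(self.methods.values())))

    def method_names(self):
        return list(self.methods)


@dataclass
class SSEPool:
    """Candidate SSEs; entries may overlap and repeat regions."""

    entries: list
    source: str = ""

    def __post_init__(self):
        self.entries = sorted(set(self.entries), key=lambda e: (e.first, e.last, e.ss_type))
        for e in self.entries:
            if e.last < e.first or e.first < 1:
                raise PoolError(f"bad entry bounds {e}")
            if e.last - e.first + 1 < MIN_SSE_LENGTH[e.ss_type]:
                raise PoolError(f"entry below minimum length: {e}")

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def has_type(self, ss_type: str) -> bool:
        return any(e.ss_type == ss_type for e in self.entries)

    def covered_mask(self, seq_length: int) -> np.ndarray:
        mask = np.zeros(seq_length, dtype=bool)
        for e in self.entries:
            mask[e.first - 1 : e.last] = True
        return mask


@dataclass
class PoolMetrics:
    q3: float        # percent of residues with correct 3-state label
    pct_found: float  # percent of native SSEs matched by a same-type entry
    shift: float     # mean |d first| + |d last| over matched native SSEs


# ---------------------------------------------------------------------------
# Assignment helpers
# ---------------------------------------------------------------------------


def _assignment_from_probs(probs: np.ndarray, threshold: float) -> np.ndarray:
    """Argmax 3-state assignment with sub-threshold H/E demoted to coil."""
    idx = probs.argmax(axis=1)
    labels = np.array([STATES[i] for i in idx])
    winning = probs[np.arange(len(probs)), idx]
    labels[(labels != "C") & (winning < threshold)] = "C"
    return labels


def _entries_from_assignment(labels, min_h: int, min_s: int):
    """Maximal H/E runs satisfying minimum lengths, as PoolEntry list."""
    entries = []
    i = 0
    L = len(labels)
    while i < L:
        state = labels[i]
        j = i
        while j < L and labels[j] == state:
            j += 1
        if state in ("H", "E"):
            run = j - i
            min_len = min_h if state == "H" else min_s
            if run >= min_len:
                entries.append(PoolEntry(_TYPE_OF_STATE[state], i + 1, j))
        i = j
    return entries


def assignment_from_pool(pool: SSEPool, length: int, pred: SSPrediction | None = None) -> np.ndarray:
    """Per-residue 3-state labels implied by a pool.

    A residue covered by any entry takes that entry's state (helix/strand
    beat coil).  If both a helix and a strand entry cover the residue, the
    state with the higher mean predicted probability wins when predictions
    are available, otherwise helix wins (documented tie-break).
    """
    cover_h = np.zeros(length, dtype=bool)
    cover_e = np.zeros(length, dtype=bool)
    for e in pool.entries:
        sl = slice(e.first - 1, e.last)
        (cover_h if e.ss_type == "helix" else cover_e)[sl] = True
    labels = np.full(length, "C")
    labels[cover_h] = "H"
    labels[cover_e] = "E"
    both = cover_h & cover_e
    if both.any():
        if pred is not None:
            mean_probs = np.mean([p for p in pred.methods.values()], axis=0)
            labels[both] = np.where(
                mean_probs[both, 0] >= mean_probs[both, 1], "H", "E"
            )
        else:
            labels[both] = "H"
    return labels


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def initial_pool(
    pred: SSPrediction,
    threshold: float = 0.5,
    min_h: int = MIN_SSE_LENGTH["helix"],
    min_s: int = MIN_SSE_LENGTH["strand"],
) -> SSEPool:
    """Threshold-and-filter pool: union over methods of maximal H/E runs.

    Per method, each residue gets its argmax state, demoted to coil when the
    winning helix/strand probability is below ``threshold``; runs shorter
    than the minimum lengths are dropped; duplicate entries collapse.
    """
    if pred.length < 1:
        raise PoolError("empty prediction")
    entries = []
    for probs in pred.methods.values():
        labels = _assignment_from_probs(probs, threshold)
        entries.extend(_entries_from_assignment(labels, min_h, min_s))
    return SSEPool(entries, source="initial")


def pool_agreement_score(assignment, pred: SSPrediction) -> float:
    """Negative log-likelihood of an assignment under the predictions.

    Sum over residues, averaged over methods, of -log p(assigned state),
    floored at ``PROB_FLOOR``.  Lower is better.
    """
    labels = np.asarray(assignment)
    if len(labels) != pred.length:
        raise PoolError("assignment length does not match prediction")
    state_idx = np.array([STATES.index(s) for s in labels])
    per_method = []
    for probs in pred.methods.values():
        p = probs[np.arange(len(labels)), state_idx]
        per_method.append(-np.log(np.maximum(p, PROB_FLOOR)))
    return float(np.mean(per_method, axis=0).sum())


def _runs_valid(labels, min_h: int, min_s: int) -> bool:
    i, L = 0, len(labels)
    while i < L:
        j = i
        while j < L and labels[j] == labels[i]:
            j += 1
        if labels[i] == "H" and j - i < min_h:
            return False
        if labels[i] == "E" and j - i < min_s:
            return False
        i = j
    return True


def refine_pool(
    pool: SSEPool,
    pred: SSPrediction,
    steps: int = 1000,
    seed: int = 0,
    min_h: int = MIN_SSE_LENGTH["helix"],
    min_s: int = MIN_SSE_LENGTH["strand"],
) -> SSEPool:
    """Greedy Monte Carlo refinement of the pool's implied assignment.

    Each step proposes changing one residue's 3-state label (which can also
    divide an SSE by demoting an interior residue to coil); proposals that
    would create an under-length helix/strand run are rejected, and only
    score-improving proposals are accepted, so the agreement score never
    increases.  Deterministic for a fixed seed.
    """
    if steps < 1:
        raise PoolError("steps must be >= 1")
    rng = np.random.default_rng(seed)
    L = pred.length
    labels = assignment_from_pool(pool, L, pred)
    score = pool_agreement_score(labels, pred)
    for _ in range(steps):
        i = int(rng.integers(L))
        new_state = STATES[int(rng.integers(3))]
        if labels[i] == new_state:
            continue
        trial = labels.copy()
        trial[i] = new_state
        if not _runs_valid(trial, min_h, min_s):
            continue
        trial_score = pool_agreement_score(trial, pred)
        if trial_score < score:
            labels, score = trial, trial_score
    refined = SSEPool(
        _entries_from_assignment(labels, min_h, min_s), source="refined"
    )
    # Guard: if the input pool implied under-length runs (overlapping H/E
    # entries can fragment a run), extraction may alter the assignment; never
    # return a pool scoring worse than the input.
    final_score = pool_agreement_score(
        assignment_from_pool(refined, L, pred), pred
    )
    initial_score = pool_agreement_score(assignment_from_pool(pool, L, pred), pred)
    if final_score > initial_score:
        return pool
    return refined


def evaluate_pool(
    pool: SSEPool,
    native_labels,
    native_sses,
    pred: SSPrediction | None = None,
) -> PoolMetrics:
    """Q3 / %found / shift of a pool versus a native assignment.

    ``native_labels`` is the per-residue H/E/C assignment; ``native_sses``
    the native SSE list as (ss_type, first, last).  A native SSE counts as
    found when at least one same-type pool entry overlaps it; its shift is
    the minimum |d first| + |d last| over those entries.
    """
    native_labels = np.asarray(native_labels)
    if not len(native_sses):
        raise PoolError("empty native SSE list: %found undefined")
    L = len(native_labels)
    pool_labels = assignment_from_pool(pool, L, pred)
    q3 = 100.0 * float((pool_labels == native_labels).mean())
    shifts = []
    n_found = 0
    for nat in native_sses:
        nat = PoolEntry(*nat)
        matches = [
            abs(e.first - nat.first) + abs(e.last - nat.last)
            for e in pool.entries
            if e.ss_type == nat.ss_type
            and not (e.last < nat.first or e.first > nat.last)
        ]
        if matches:
            n_found += 1
            shifts.append(min(matches))
    pct_found = 100.0 * n_found / len(native_sses)
    shift = float(np.mean(shifts)) if shifts else 0.0
    return PoolMetrics(q3=q3, pct_found=pct_found, shift=shift)
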