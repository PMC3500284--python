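"""Monte Carlo Metropolis engine with adaptive temperature.

Each step proposes a move, scores the resulting model, and classifies the
step as one of four outcomes: "improved" (below the reference energy,
always taken and promoted to best), "accepted" (uphill but admitted by the
Metropolis criterion; the working model advances, the best does not),
"rejected" (the search resumes from the best model) or "skipped" (the move's
prerequisites were absent; no energy evaluation).  The reference energy for
the Metropolis comparison is the energy of the BEST model observed so far --
this is the documented protocol, not the conventional last-accepted energy;
``RunConfig.compare_to_best=False`` switches to the conventional rule.

Temperature starts at 500 su and is adjusted every 10th step so that the
cumulative acceptance ratio of non-skipped steps tracks a target that falls
linearly from 0.5 to 0.2 over the stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig, StageSchedule, TemperatureSettings
from .energy import score_model
from .geometry import ProteinModel, build_ideal_sse
from .moves import SKIPPED, MoveSet, build_move_set, propose
from .pool import SSEPool, SSPrediction

OUTCOMES = ("improved", "accepted", "rejected", "skipped")


class MinimizerError(RuntimeError):
    pass


class StagnationError(MinimizerError):
    """Every move in the set was inapplicable for a full non-improving sweep."""


@dataclass
class StepRecord:
    step: int
    move: str
    outcome: str
    e_new: float
    e_best: float
    temperature: float


@dataclass
class Trajectory:
    stage: str
    steps: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.steps)

    def __len__(self):
        return len(self.steps)

    def outcome_counts(self) -> dict:
        counts = {o: 0 for o in OUTCOMES}
        for rec in self.steps:
            counts[rec.outcome] += 1
        return counts


@dataclass
class TemperatureController:
    settings: TemperatureSettings = field(default_factory=TemperatureSettings)
    temperature: float = None

    def __post_init__(self):
        if self.temperature is None:
            self.temperature = self.settings.t0


def metropolis_decide(e_new: float, e_ref: float, temperature: float, rng,
                      k: float = 1.0) -> str:
    """Classify a proposal: improved (always), accepted (probability
    exp(-dE/kT)) or rejected."""
    if not (math.isfinite(e_new) and math.isfinite(e_ref)):
        raise MinimizerError("non-finite energies in Metropolis evaluation")
    if temperature <= 0:
        raise MinimizerError("temperature must be positive")
    if e_new < e_ref:
        return "improved"
    p = math.exp(-(e_new - e_ref) / (k * temperature))
    return "accepted" if rng.random() < p else "rejected"


def step_bookkeeping(outcome: str, proposal, working, best):
    """(next working model, next best model) for one step outcome."""
    if outcome == "improved":
        return proposal, proposal
    if outcome == "accepted":
        return proposal, best
    # rejected or skipped: resume from the best model observed so far
    return best, best


def update_temperature(ctrl: TemperatureController, outcomes, progress: float) -> float:
    """Adjust temperature toward the linearly falling acceptance target.

    ``outcomes`` is the full outcome history of the stage; the cumulative
    acceptance ratio counts improved+accepted over non-skipped steps.  If
    the ratio is below the target the temperature is raised by 5%, else
    lowered by 5% (ties cool), clamped to the configured bounds.
    """
    non_skipped = sum(1 for o in outcomes if o != "skipped")
    accepted = sum(1 for o in outcomes if o in ("improved", "accepted"))
    return _update_temperature_counts(ctrl, accepted, non_skipped, progress)


def _update_temperature_counts(ctrl, accepted: int, non_skipped: int,
                               progress: float) -> float:
    s = ctrl.settings
    ratio = accepted / non_skipped if non_skipped else 0.0
    target = s.target(progress)
    factor = s.heat_factor if ratio < target else s.cool_factor
    ctrl.temperature = float(np.clip(ctrl.temperature * factor, s.t_min, s.t_max))
    return ctrl.temperature


def run_stage(
    model0: ProteinModel,
    move_set: MoveSet,
    scorer,
    schedule: StageSchedule,
    ctrl: TemperatureController,
    rng,
    pool: SSEPool,
    move_cfg,
    compare_to_best: bool = True,
):
    """One minimization stage; returns (best model, trajectory).

    Terminates at ``schedule.max_steps`` total steps or after
    ``schedule.max_nonimproving`` consecutive steps that did not improve the
    score (accepted, rejected and skipped all count as non-improving).
    """
    working = best = model0
    e_working = e_best = scorer(model0)
    traj = Trajectory(stage=schedule.stage)
    n_non_skipped = 0
    n_accepted = 0
    consecutive = 0
    any_applicable = False
    k = ctrl.settings.k
    for step in range(1, schedule.max_steps + 1):
        move = move_set.sample(rng)
        proposal = propose(move, working, pool, rng, move_cfg)
        if proposal is SKIPPED or isinstance(proposal, str):
            outcome = "skipped"
            e_new = math.nan
        else:
            any_applicable = True
            e_new = scorer(proposal)
            e_ref = e_best if compare_to_best else e_working
            outcome = metropolis_decide(e_new, e_ref, ctrl.temperature, rng, k)
            working, best = step_bookkeeping(outcome, proposal, working, best)
            if outcome == "improved":
                e_best = e_new
                e_working = e_new
            elif outcome == "accepted":
                e_working = e_new
            else:
                e_working = e_best
        if outcome != "skipped":
            n_non_skipped += 1
            if outcome in ("improved", "accepted"):
                n_accepted += 1
        traj.steps.append(
            StepRecord(step, move.name, outcome, e_new, e_best, ctrl.temperature)
        )
        consecutive = 0 if outcome == "improved" else consecutive + 1
        if step % ctrl.settings.adjust_every == 0:
            _update_temperature_counts(
                ctrl, n_accepted, n_non_skipped, step / schedule.max_steps
            )
        if consecutive >= schedule.max_nonimproving:
            if not any_applicable:
                raise StagnationError(
                    f"{schedule.stage}: no applicable move in "
                    f"{consecutive} consecutive steps"
                )
            break
    return best, traj


def initial_model(sequence: str, pool: SSEPool, rng) -> ProteinModel:
    """A model holding one randomly drawn pool SSE in its canonical frame."""
    entry = pool.entries[int(rng.integers(len(pool)))]
    sse = build_ideal_sse(
        sequence[entry.first - 1 : entry.last], entry.first, entry.last,
        entry.ss_type,
    )
    return ProteinModel(sequence, [sse], provenance=pool.source)


@dataclass
class FoldResult:
    model: ProteinModel
    energy: float
    trajectories: list  # [assembly, refinement]
    seed: int


def fold(
    sequence: str,
    pool: SSEPool,
    pred: SSPrediction | None,
    config: RunConfig = None,
    n_models: int = 1,
    seed: int = 0,
) -> list:
    """Full two-stage protocol: returns FoldResults sorted by final energy.

    Each model starts from one random pool SSE at the origin, runs the
    assembly stage, then the refinement stage.  The per-model random stream
    is derived deterministically from (seed, model index).
    """
    if len(pool) == 0:
        raise MinimizerError("empty pool")
    if config is None:
        config = RunConfig()

    def scorer(m):
        return score_model(m, pred, config.weights, config.energy).total

    results = []
    for index in range(n_models):
        rng = np.random.default_rng([seed, index])
        model = initial_model(sequence, pool, rng)
        trajectories = []
        for schedule in (config.assembly, config.refinement):
            move_set = build_move_set(pool, schedule.stage, config.move)
            ctrl = TemperatureController(config.temperature)
            model, traj = run_stage(
                model, move_set, scorer, schedule, ctrl, rng, pool,
                config.move, config.compare_to_best,
            )
            trajectories.append(traj)
        results.append(FoldResult(model, scorer(model), trajectories, index))
    results.sort(key=lambda r: r.energy)
    return results
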