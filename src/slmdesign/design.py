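"""Ab initio enhancer design by simulated annealing.

The designer searches DNA sequence space for a sequence whose model-predicted
expression matches a target profile.  The cost of a candidate sequence under
one parameter set is

    E = sum_i (x_i - y_i)^2  +  beta * o ,

where x is the predicted profile, y the target, and o the number of pairs of
called binding motifs (LLR > 0, any factors) whose footprints overlap or lie
within ``overlap_gap`` (default 5) bp of each other end to end; the beta*o
term penalises crowded binding-site arrangements.  By default beta is 1% of
the maximum possible sum-of-squares score, i.e. 0.01 * n_bins * 255^2 (all
bins at the display maximum of 255 against a zero target).  Consensus design
over k parameter sets minimises the arithmetic mean of the k per-set costs.

The search proposes single-nucleotide substitutions at uniformly random
positions with Metropolis acceptance under a geometric cooling schedule,
starting from a supplied or random sequence, and is fully reproducible from
its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .motifs import ALPHABET, Background, BindingSite, Pwm
from .params import ParameterSet
from .profiles import ExpressionProfile, TfProfile
from .thermo import annotate_sites, predict_expression

__all__ = [
    "default_beta",
    "DesignObjective",
    "AnnealSchedule",
    "count_overlaps",
    "cost_from_profiles",
    "design_cost",
    "consensus_cost",
    "anneal_sequence",
]

MAX_DISPLAY = 255.0


def default_beta(n_bins: int, max_display: float = MAX_DISPLAY) -> float:
    """1% of the maximum possible sum-of-squares score (all bins at 255)."""
    return 0.01 * n_bins * max_display**2


@dataclass(frozen=True)
class DesignObjective:
    target: ExpressionProfile
    parameter_sets: tuple[ParameterSet, ...]
    catalogue: dict[str, Pwm]
    atlas: tuple[TfProfile, ...]
    beta: float | None = None
    overlap_gap: int = 5
    background: Background = field(default_factory=Background)

    def __post_init__(self) -> None:
        if not self.parameter_sets:
            raise ValueError("at least one parameter set is required")
        if self.beta is not None and self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.overlap_gap < 0:
            raise ValueError("overlap_gap must be >= 0")

    @property
    def effective_beta(self) -> float:
        if self.beta is not None:
            return self.beta
        return default_beta(self.target.grid.size)


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling: ``stages`` stages of ``moves_per_stage`` moves, the
    temperature multiplied by ``cooling`` after each stage."""

    initial_temperature: float = 2000.0
    cooling: float = 0.9
    moves_per_stage: int = 200
    stages: int = 30
    seed: int = 0
    stall_stages: int | None = None  # stop early after this many stages w/o improvement

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling factor must lie in (0, 1)")
        if self.initial_temperature <= 0:
            raise ValueError("initial temperature must be positive")
        if self.moves_per_stage * self.stages <= 0:
            raise ValueError("schedule must perform at least one move")


def count_overlaps(sites: list[BindingSite], gap: int = 5) -> int:
    """Number of unordered site pairs whose footprints overlap or whose
    end-to-end distance is within ``gap`` bp (inclusive)."""
    starts = [s.start for s in sites]
    if any(starts[i] > starts[i + 1] for i in range(len(sites) - 1)):
        raise ValueError("sites must be sorted by start position")
    o = 0
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            if sites[j].start - sites[i].end > gap:
                break  # sorted by start: no later j can be close enough
            o += 1
    return o


def cost_from_profiles(
    x: np.ndarray, y: np.ndarray, overlaps: int, beta: float
) -> float:
    """The design cost given already-computed profiles: SSE plus beta * o."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("model and target profiles have different lengths")
    return float(np.sum((x - y) ** 2) + beta * overlaps)


def design_cost(
    seq: str, objective: DesignObjective, parameter_set: ParameterSet | None = None
) -> float:
    """Cost under a single parameter set (the objective's only one by default)."""
    if parameter_set is None:
        if len(objective.parameter_sets) != 1:
            raise ValueError(
                "objective holds several parameter sets; pass one explicitly "
                "or use consensus_cost"
            )
        parameter_set = objective.parameter_sets[0]
    x = predict_expression(
        seq, objective.atlas, parameter_set, objective.catalogue, objective.background
    )
    y = objective.target
    if not x.same_grid(y):
        raise ValueError("target grid does not match the atlas grid")
    sites = annotate_sites(seq, objective.catalogue, parameter_set, objective.background)
    return cost_from_profiles(
        x.values, y.values,
        count_overlaps(sites, objective.overlap_gap), objective.effective_beta,
    )


def consensus_cost(seq: str, objective: DesignObjective) -> float:
    """Arithmetic mean of the per-set design costs (order-invariant)."""
    costs = [design_cost(seq, objective, ps) for ps in objective.parameter_sets]
    return float(np.mean(costs))


def anneal_sequence(
    initial: str,
    objective: DesignObjective,
    schedule: AnnealSchedule,
) -> tuple[str, list[float]]:
    """Minimise the (consensus) design cost by simulated annealing.

    ``initial`` is either a DNA string or ``"random:L"`` for a random start of
    length L drawn from the objective's background.  Returns the best-ever
    sequence and the per-stage best-cost trace (nonincreasing).
    """
    rng = np.random.default_rng(schedule.seed)
    if initial.startswith("random:"):
        length = int(initial.split(":", 1)[1])
        if length < 1:
            raise ValueError("random initial length must be >= 1")
        probs = objective.background.array
        current = "".join(rng.choice(list(ALPHABET), size=length, p=probs))
    else:
        current = initial.upper()
    min_len = max(len(p) for p in objective.catalogue.values())
    if len(current) < min_len:
        raise ValueError(
            f"design length {len(current)} is shorter than the longest PWM ({min_len})"
        )

    cost = consensus_cost(current, objective)
    best, best_cost = current, cost
    trace = []
    temperature = schedule.initial_temperature
    stalled = 0
    for _stage in range(schedule.stages):
        stage_improved = False
        for _ in range(schedule.moves_per_stage):
            pos = int(rng.integers(len(current)))
            new_base = ALPHABET[int(rng.integers(4))]
            if new_base == current[pos]:
                continue
            candidate = current[:pos] + new_base + current[pos + 1 :]
            cand_cost = consensus_cost(candidate, objective)
            delta = cand_cost - cost
            if delta <= 0 or rng.random() < math.exp(-delta / temperature):
                current, cost = candidate, cand_cost
                if cost < best_cost:
                    best, best_cost = current, cost
                    stage_improved = True
        trace.append(best_cost)
        temperature *= schedule.cooling
        stalled = 0 if stage_improved else stalled + 1
        if schedule.stall_stages is not None and stalled >= schedule.stall_stages:
            break
        if best_cost == 0.0:
            break
    return best, trace
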