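"""Synthetic compensatory evolution: Levenshtein edit scripts and neutral paths.

Two enhancers are separated by their Levenshtein edits (LE): the minimal set
of single-nucleotide substitutions, insertions and deletions converting one
into the other.  A *neutral path* is an ordering of those edits chosen so
that the model-predicted stripe expression is conserved as well as possible
at every intermediate sequence.

Each intermediate is scored against the reference profile y with the
shape cost

    F = sum_i ( x_i / max_j x_j  -  y_i / max_j y_j )^2  *  Penalty ,

    Penalty = max_i y_i / max_i x_i   if max_i x_i < max_i y_i, else 1 ,

which standardises both profiles to unit maximum and multiplicatively
penalises under-expression.  A silent intermediate (max x = 0) scores +inf.
The path objective is the sum of F over every intermediate sequence and
every scoring parameter set.  (When two shapes are identical the penalty
multiplies a zero sum and is inert; the cost is implemented exactly as
defined.)

Edits are anchored to columns of the source-target alignment rather than to
mutable sequence offsets, so applying them in any order is well defined and
always reaches the target.  Order optimisation is greedy (apply the
remaining edit whose resulting sequence scores best), optionally refined by
seeded simulated annealing over the permutation; exhaustive search is
available for short scripts.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .motifs import Background, Pwm
from .params import ParameterSet
from .profiles import ExpressionProfile, TfProfile
from .thermo import predict_expression

__all__ = [
    "Edit",
    "EditScript",
    "NeutralPath",
    "levenshtein_script",
    "step_cost",
    "sum_step_cost",
    "make_step_scorer",
    "path_objective",
    "optimize_edit_order",
]

_VALID = set("ACGT")


def _check_dna(seq: str, label: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{label} sequence contains non-ACGT characters {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class Edit:
    """One edit, anchored to a column of the source-target alignment."""

    kind: str  # substitution | insertion | deletion
    column: int
    source_base: str | None
    target_base: str | None


@dataclass(frozen=True)
class EditScript:
    """Minimal edit script between two sequences, with its alignment.

    ``columns`` is the full pairwise alignment as (source char | None,
    target char | None) pairs; ``edits`` are the columns where they differ,
    in left-to-right column order.  ``len(edits)`` equals the Levenshtein
    distance.
    """

    source: str
    target: str
    columns: tuple[tuple[str | None, str | None], ...] = field(repr=False)
    edits: tuple[Edit, ...] = field(repr=False)

    @property
    def distance(self) -> int:
        return len(self.edits)

    def apply(self, applied: Sequence[int] | set[int]) -> str:
        """Sequence obtained by applying the given subset of edit indices."""
        applied = set(applied)
        edit_by_col = {self.edits[i].column: i for i in range(len(self.edits))}
        out = []
        for col, (s, t) in enumerate(self.columns):
            i = edit_by_col.get(col)
            ch = t if (i is not None and i in applied) else s
            if ch is not None:
                out.append(ch)
        return "".join(out)

    def edit_position(self, edit_index: int, applied: Sequence[int] | set[int]) -> int:
        """0-based position of an edit in current-sequence coordinates, i.e.
        in the sequence produced by ``apply(applied)``."""
        applied = set(applied)
        edit_by_col = {self.edits[i].column: i for i in range(len(self.edits))}
        pos = 0
        for col, (s, t) in enumerate(self.columns):
            if col == self.edits[edit_index].column:
                return pos
            i = edit_by_col.get(col)
            ch = t if (i is not None and i in applied) else s
            if ch is not None:
                pos += 1
        raise IndexError(edit_index)


def levenshtein_script(source: str, target: str) -> EditScript:
    """Minimal-length edit script under unit costs, with deterministic
    tie-breaking (substitution preferred over deletion over insertion,
    backtraced from the end so edits come out leftmost-first)."""
    a = _check_dna(source, "source")
    b = _check_dna(target, "target")
    n, m = len(a), len(b)
    d = np.zeros((n + 1, m + 1), dtype=np.int32)
    d[:, 0] = np.arange(n + 1)
    d[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        row, prev = d[i], d[i - 1]
        for j in range(1, m + 1):
            row[j] = min(
                prev[j - 1] + (ai != b[j - 1]),
                prev[j] + 1,      # delete a[i-1]
                row[j - 1] + 1,   # insert b[j-1]
            )
    columns: list[tuple[str | None, str | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and d[i, j] == d[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            columns.append((a[i - 1], b[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and d[i, j] == d[i - 1, j] + 1:
            columns.append((a[i - 1], None))
            i -= 1
        else:
            columns.append((None, b[j - 1]))
            j -= 1
    columns.reverse()
    edits = []
    for col, (s, t) in enumerate(columns):
        if s == t:
            continue
        kind = "substitution" if s and t else ("deletion" if t is None else "insertion")
        edits.append(Edit(kind, col, s, t))
    return EditScript(a, b, tuple(columns), tuple(edits))


def step_cost(x: ExpressionProfile, y: ExpressionProfile) -> float:
    """Shape cost F of a model profile x against a reference y (see module
    docstring).  Returns +inf for a silent model profile."""
    if x.grid.size != y.grid.size or not np.allclose(x.grid, y.grid):
        raise ValueError("profiles are on different AP grids")
    ymax = y.values.max()
    if ymax <= 0:
        raise ValueError("reference profile is identically zero")
    xmax = x.values.max()
    if xmax <= 0:
        return math.inf
    sse = float(np.sum((x.values / xmax - y.values / ymax) ** 2))
    penalty = ymax / xmax if xmax < ymax else 1.0
    return sse * penalty


def make_step_scorer(
    reference: ExpressionProfile,
    parameter_sets: Sequence[ParameterSet],
    atlas: Sequence[TfProfile],
    catalogue: dict[str, Pwm],
    bg: Background | None = None,
) -> Callable[[str], float]:
    """Scorer mapping a sequence to sum over parameter sets of F against the
    reference profile, using model predictions only."""
    atlas = tuple(atlas)
    sets = tuple(parameter_sets)
    if not sets:
        raise ValueError("at least one scoring parameter set is required")

    def scorer(seq: str) -> float:
        return sum(
            step_cost(predict_expression(seq, atlas, ps, catalogue, bg), reference)
            for ps in sets
        )

    return scorer


def sum_step_cost(scores: Sequence[float]) -> float:
    return float(sum(scores))


def path_objective(
    script: EditScript,
    order: Sequence[int],
    scorer: Callable[[str], float],
) -> float:
    """Total cost of a path: sum of the scorer over every intermediate
    sequence (steps 1..k; the final one is the fixed target)."""
    if sorted(order) != list(range(script.distance)):
        raise ValueError("order must be a permutation of all edit indices")
    total = 0.0
    applied: set[int] = set()
    for idx in order:
        applied.add(idx)
        total += scorer(script.apply(applied))
    return total


@dataclass(frozen=True)
class NeutralPath:
    script: EditScript
    order: tuple[int, ...]
    step_sequences: tuple[str, ...]  # step 0 = source ... step k = target
    step_costs: tuple[float, ...]    # scorer value per intermediate (len k)
    step_rms: tuple[float, ...]      # rms vs reference per intermediate (len k)
    set_ids: tuple[int, ...]
    seed: int

    @property
    def total_cost(self) -> float:
        return float(sum(self.step_costs))


def _path_rms(seq_profile: ExpressionProfile, reference: ExpressionProfile) -> float:
    return float(
        np.sqrt(np.mean((seq_profile.values - reference.values) ** 2))
    )


def optimize_edit_order(
    script: EditScript,
    scorer: Callable[[str], float],
    strategy: str = "greedy+anneal",
    seed: int = 0,
    anneal_moves: int = 200,
    anneal_temperature: float = 1.0,
    rms_fn: Callable[[str], float] | None = None,
    set_ids: Sequence[int] = (),
) -> NeutralPath:
    """Order the edits of a script to conserve predicted expression.

    ``strategy``: 'greedy', 'greedy+anneal', or 'exhaustive' (scripts of
    <= 8 edits only).  Ties break toward the lowest edit index, so a script
    whose edits never change the score comes out in left-to-right order.
    """
    k = script.distance
    if strategy not in ("greedy", "greedy+anneal", "exhaustive"):
        raise ValueError(f"unknown strategy {strategy!r}")

    if strategy == "exhaustive":
        if k > 8:
            raise ValueError("exhaustive search is limited to scripts of <= 8 edits")
        best_order, best_total = None, math.inf
        for perm in itertools.permutations(range(k)):
            total = path_objective(script, perm, scorer)
            if total < best_total:
                best_order, best_total = perm, total
        order = list(best_order if best_order is not None else range(k))
    else:
        order = []
        applied: set[int] = set()
        remaining = list(range(k))
        while remaining:
            costs = []
            for idx in remaining:
                seq = script.apply(applied | {idx})
                costs.append((scorer(seq), idx))
            _, chosen = min(costs)  # ties -> lowest edit index
            order.append(chosen)
            applied.add(chosen)
            remaining.remove(chosen)
        if strategy == "greedy+anneal" and k > 1:
            order = _anneal_order(
                script, order, scorer, seed, anneal_moves, anneal_temperature
            )

    step_sequences = [script.source]
    step_costs, step_rms = [], []
    applied = set()
    for idx in order:
        applied.add(idx)
        seq = script.apply(applied)
        step_sequences.append(seq)
        step_costs.append(scorer(seq))
        step_rms.append(rms_fn(seq) if rms_fn else math.nan)
    return NeutralPath(
        script, tuple(order), tuple(step_sequences), tuple(step_costs),
        tuple(step_rms), tuple(set_ids), seed,
    )


def _anneal_order(
    script: EditScript,
    order: list[int],
    scorer: Callable[[str], float],
    seed: int,
    moves: int,
    temperature: float,
) -> list[int]:
    """Refine a permutation by Metropolis swaps of two order positions."""
    rng = np.random.default_rng(seed)
    k = len(order)

    def step_scores(o: list[int]) -> list[float]:
        scores, applied = [], set()
        for idx in o:
            applied.add(idx)
            scores.append(scorer(script.apply(applied)))
        return scores

    scores = step_scores(order)
    best_order, best_total = list(order), sum(scores)
    total = best_total
    t = temperature
    for _ in range(moves):
        a, b = sorted(rng.choice(k, size=2, replace=False))
        cand = list(order)
        cand[a], cand[b] = cand[b], cand[a]
        # steps a..b-1 change; step b onward sees the same applied set
        cand_scores = list(scores)
        applied = set(cand[:a])
        for pos in range(a, b + 1):
            applied.add(cand[pos])
            cand_scores[pos] = scorer(script.apply(applied))
        cand_total = sum(cand_scores)
        delta = cand_total - total
        if delta <= 0 or (
            math.isfinite(delta) and rng.random() < math.exp(-delta / t)
        ):
            order, scores, total = cand, cand_scores, cand_total
            if total < best_total:
                best_order, best_total = list(order), total
        t *= 0.995
    return best_order
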