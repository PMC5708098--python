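"""Binding-site turnover between two enhancer sequences.

Sites are called independently on both sequences (LLR > 0 against the
genomic background), the sequences are globally aligned, and each site in
the reference sequence A is classified as *maintained* if a site for the
same factor on sequence B starts within a tolerance (default 3 bp) of it in
alignment coordinates, else *lost*; B-sites with no A-site partner within
tolerance are *gained*.  Matching is per-factor, one-to-one, greedy
nearest-first, and strand-agnostic (a site that flips strand in place still
confers the same affinity and counts as maintained).
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .motifs import Background, BindingSite, Pwm, scan_sequence

__all__ = ["AlignmentScoring", "AlignedPair", "TurnoverReport",
           "global_align", "classify_sites", "compare_sequences"]


@dataclass(frozen=True)
class AlignmentScoring:
    """Needleman-Wunsch scoring; defaults chosen for ~50%-identity DNA."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class AlignedPair:
    seq_a: str
    seq_b: str
    aligned_a: str = field(repr=False)
    aligned_b: str = field(repr=False)
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.aligned_a.replace("-", "") != self.seq_a:
            raise ValueError("degapped aligned A does not equal input A")
        if self.aligned_b.replace("-", "") != self.seq_b:
            raise ValueError("degapped aligned B does not equal input B")

    def column_of_a(self, pos: int) -> int:
        """Alignment column of 0-based position ``pos`` in sequence A."""
        return self._column(self.aligned_a, pos)

    def column_of_b(self, pos: int) -> int:
        return self._column(self.aligned_b, pos)

    @staticmethod
    def _column(aligned: str, pos: int) -> int:
        count = -1
        for col, ch in enumerate(aligned):
            if ch != "-":
                count += 1
                if count == pos:
                    return col
        raise IndexError(f"position {pos} beyond sequence of length {count + 1}")


def global_align(
    seq_a: str, seq_b: str, scoring: AlignmentScoring | None = None
) -> AlignedPair:
    """Global (Needleman-Wunsch) alignment with a deterministic backtrace."""
    scoring = scoring or AlignmentScoring()
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be nonempty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    alignments = aligner.align(seq_a, seq_b)
    best = alignments[0]  # deterministic first backtrace
    a_str, b_str = str(best[0]), str(best[1])
    return AlignedPair(seq_a, seq_b, a_str, b_str, float(best.score))


@dataclass(frozen=True)
class TurnoverReport:
    maintained: dict[str, int]
    gained: dict[str, int]
    lost: dict[str, int]
    maintained_sites: tuple[tuple[BindingSite, BindingSite], ...] = field(repr=False)
    gained_sites: tuple[BindingSite, ...] = field(repr=False)
    lost_sites: tuple[BindingSite, ...] = field(repr=False)

    @property
    def total_maintained(self) -> int:
        return sum(self.maintained.values())

    @property
    def total_gained(self) -> int:
        return sum(self.gained.values())

    @property
    def total_lost(self) -> int:
        return sum(self.lost.values())

    @property
    def total_a_sites(self) -> int:
        return self.total_maintained + self.total_lost

    @property
    def percent_maintained(self) -> float:
        n = self.total_a_sites
        return 100.0 * self.total_maintained / n if n else float("nan")

    @property
    def percent_lost(self) -> float:
        n = self.total_a_sites
        return 100.0 * self.total_lost / n if n else float("nan")


def classify_sites(
    pair: AlignedPair,
    sites_a: list[BindingSite],
    sites_b: list[BindingSite],
    tolerance: int = 3,
) -> TurnoverReport:
    """Classify reference sites as maintained/lost and alternate sites as
    gained, matching per factor within ``tolerance`` alignment columns
    (inclusive) of the site-start anchor."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    for s in sites_a:
        if s.end > len(pair.seq_a):
            raise ValueError(f"A-site {s} extends beyond sequence A")
    for s in sites_b:
        if s.end > len(pair.seq_b):
            raise ValueError(f"B-site {s} extends beyond sequence B")

    factors = sorted({s.factor_name for s in sites_a} | {s.factor_name for s in sites_b})
    maintained: dict[str, int] = {f: 0 for f in factors}
    gained: dict[str, int] = {f: 0 for f in factors}
    lost: dict[str, int] = {f: 0 for f in factors}
    pairs: list[tuple[BindingSite, BindingSite]] = []
    gained_sites: list[BindingSite] = []
    lost_sites: list[BindingSite] = []

    for factor in factors:
        fa = [s for s in sites_a if s.factor_name == factor]
        fb = [s for s in sites_b if s.factor_name == factor]
        cols_a = [pair.column_of_a(s.start) for s in fa]
        cols_b = [pair.column_of_b(s.start) for s in fb]
        # greedy nearest-first one-to-one matching
        candidates = sorted(
            (abs(ca - cb), i, j)
            for i, ca in enumerate(cols_a)
            for j, cb in enumerate(cols_b)
            if abs(ca - cb) <= tolerance
        )
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _, i, j in candidates:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            pairs.append((fa[i], fb[j]))
        maintained[factor] = len(used_a)
        lost[factor] = len(fa) - len(used_a)
        gained[factor] = len(fb) - len(used_b)
        lost_sites.extend(s for i, s in enumerate(fa) if i not in used_a)
        gained_sites.extend(s for j, s in enumerate(fb) if j not in used_b)

    return TurnoverReport(
        maintained, gained, lost, tuple(pairs), tuple(gained_sites), tuple(lost_sites)
    )


def compare_sequences(
    seq_a: str,
    seq_b: str,
    catalogue: Mapping[str, Pwm],
    factors: list[str] | None = None,
    bg: Background | None = None,
    tolerance: int = 3,
    scoring: AlignmentScoring | None = None,
) -> TurnoverReport:
    """Full turnover analysis: scan both sequences (LLR > 0, both strands),
    align, and classify."""
    bg = bg or Background()
    factors = factors if factors is not None else sorted(catalogue)
    sites_a: list[BindingSite] = []
    sites_b: list[BindingSite] = []
    for f in factors:
        if f not in catalogue:
            raise ValueError(f"no PWM for factor {f!r}")
        sites_a.extend(scan_sequence(seq_a, catalogue[f], bg))
        sites_b.extend(scan_sequence(seq_b, catalogue[f], bg))
    pair = global_align(seq_a, seq_b, scoring)
    return classify_sites(pair, sites_a, sites_b, tolerance)
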