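"""Position weight matrices and log-likelihood-ratio motif scanning.

A binding motif is represented by a PWM of per-position nucleotide
probabilities.  A candidate window ``w`` of the same length is scored by the
log-likelihood ratio against a fixed genomic background,

    LLR(w) = sum_j log( p_j(w_j) / p_bg(w_j) ),

in natural-log units.  A window is called a binding site when its LLR is
strictly greater than zero, i.e. when the motif model explains the sequence
better than the background does.  Scores are often reported as a fraction of
the maximum attainable LLR of the PWM (its consensus score).

The default background is the nucleotide composition of the Drosophila
genome, P(A) = P(T) = 0.297 and P(C) = P(G) = 0.203.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ALPHABET = "ACGT"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

__all__ = [
    "ALPHABET",
    "Background",
    "Pwm",
    "BindingSite",
    "llr_score",
    "max_llr",
    "scan_sequence",
    "reverse_complement",
    "read_pwm_file",
    "write_pwm_file",
    "load_pwm_directory",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_dna(seq: str, context: str = "sequence") -> None:
    for pos, ch in enumerate(seq):
        if ch not in _INDEX:
            raise ValueError(
                f"non-ACGT character {ch!r} at position {pos} in {context}"
            )


@dataclass(frozen=True)
class Background:
    """Genomic background nucleotide probabilities (order A, C, G, T)."""

    probabilities: tuple[float, float, float, float] = (0.297, 0.203, 0.203, 0.297)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (4,) or np.any(p <= 0):
            raise ValueError("background needs 4 strictly positive probabilities")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"background probabilities sum to {p.sum()}, not 1")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.probabilities, dtype=float)

    @classmethod
    def uniform(cls) -> "Background":
        return cls((0.25, 0.25, 0.25, 0.25))


@dataclass(frozen=True)
class Pwm:
    """A position weight matrix of per-position probabilities over A/C/G/T.

    ``matrix`` has shape (L, 4).  Count matrices are converted with
    ``from_counts`` which adds a pseudocount (default 0.5 per nucleotide) so
    every probability is strictly positive.
    """

    factor_name: str
    matrix: np.ndarray = field(repr=False)
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("PWM matrix must have shape (L >= 1, 4)")
        if np.any(m <= 0):
            raise ValueError("PWM probabilities must be strictly positive")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each PWM position must sum to 1")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(
        cls, factor_name: str, counts: np.ndarray, pseudocount: float = 0.5
    ) -> "Pwm":
        c = np.asarray(counts, dtype=float)
        if np.any(c < 0) or pseudocount < 0:
            raise ValueError("counts and pseudocount must be nonnegative")
        c = c + pseudocount
        if np.any(c.sum(axis=1) <= 0):
            raise ValueError("a PWM position has zero total count; raise pseudocount")
        return cls(factor_name, c / c.sum(axis=1, keepdims=True), pseudocount)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self, bg: Background) -> np.ndarray:
        """Per-position natural-log odds matrix, shape (L, 4)."""
        return np.log(self.matrix) - np.log(bg.array)


@dataclass(frozen=True)
class BindingSite:
    """A scored motif occurrence in forward coordinates, [start, end)."""

    factor_name: str
    start: int
    end: int
    strand: str
    llr: float
    llr_fraction: float

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("site end must exceed start")

    def overlaps(self, other: "BindingSite") -> bool:
        return self.start < other.end and other.start < self.end


def llr_score(window: str, pwm: Pwm, bg: Background) -> float:
    """Natural-log likelihood ratio of one window under the PWM vs background."""
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} does not match PWM length {len(pwm)}"
        )
    _validate_dna(window, "window")
    lo = pwm.log_odds(bg)
    return float(sum(lo[j, _INDEX[c]] for j, c in enumerate(window)))


def max_llr(pwm: Pwm, bg: Background) -> float:
    """Maximum attainable LLR: the consensus-window score."""
    return float(pwm.log_odds(bg).max(axis=1).sum())


def _scan_one_strand(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """LLR of every window of ``len(lo)`` over the integer-coded sequence."""
    L = lo.shape[0]
    n = codes.size - L + 1
    scores = np.zeros(n)
    for j in range(L):
        scores += lo[j, codes[j : j + n]]
    return scores


def scan_sequence(
    seq: str,
    pwm: Pwm,
    bg: Background | None = None,
    threshold: float = 0.0,
    strands: str = "both",
) -> list[BindingSite]:
    """Score every window on the requested strand(s); keep windows with LLR
    strictly above ``threshold``.

    Reverse-strand hits are reported in forward coordinates with strand '-'.
    Returns sites sorted by start (forward before reverse at equal start).
    """
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    bg = bg or Background()
    seq = seq.upper()
    _validate_dna(seq)
    L = len(pwm)
    if len(seq) < L:
        warnings.warn(
            f"sequence ({len(seq)} bp) shorter than PWM {pwm.factor_name} ({L} bp); "
            "no windows scored",
            stacklevel=2,
        )
        return []
    codes = np.fromiter((_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    lo = pwm.log_odds(bg)
    mx = max_llr(pwm, bg)
    sites: list[BindingSite] = []

    def emit(scores: np.ndarray, strand: str) -> None:
        for start in np.flatnonzero(scores > threshold):
            s = float(scores[start])
            sites.append(
                BindingSite(pwm.factor_name, int(start), int(start) + L, strand,
                            s, s / mx if mx > 0 else np.nan)
            )

    emit(_scan_one_strand(codes, lo), "+")
    if strands == "both":
        rc_codes = (3 - codes)[::-1]
        rc_scores = _scan_one_strand(rc_codes, lo)
        # window starting at i on the reverse strand covers forward [n-L-i, n-i)
        emit(rc_scores[::-1], "-")
        # rc_scores reversed: index k of reversed array is forward start k
    sites.sort(key=lambda s: (s.start, s.strand, s.factor_name))
    return sites


# -- JASPAR-style PWM text files ------------------------------------------
#
# Format: optional '>' header with the factor name, then four rows labelled
# A/C/G/T of whitespace-separated counts or probabilities.


def read_pwm_file(path: str | Path, pseudocount: float = 0.5) -> Pwm:
    path = Path(path)
    name = path.stem
    rows: dict[str, list[float]] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            continue
        fields = line.replace("[", " ").replace("]", " ").split()
        if fields[0].upper() in ("A", "C", "G", "T"):
            rows[fields[0].upper()] = [float(x) for x in fields[1:]]
        else:
            raise ValueError(f"{path}: unlabelled matrix row {line!r}")
    if sorted(rows) != ["A", "C", "G", "T"]:
        raise ValueError(f"{path}: expected rows labelled A, C, G, T; got {sorted(rows)}")
    counts = np.array([rows[c] for c in ALPHABET]).T
    if np.allclose(counts.sum(axis=1), 1.0, atol=1e-6):
        return Pwm(name, counts / counts.sum(axis=1, keepdims=True))
    return Pwm.from_counts(name, counts, pseudocount)


def write_pwm_file(pwm: Pwm, path: str | Path, counts_scale: float | None = None) -> None:
    """Write a PWM as a labelled 4-row matrix (probabilities, or scaled counts)."""
    m = pwm.matrix if counts_scale is None else pwm.matrix * counts_scale
    lines = [f">{pwm.factor_name}"]
    for i, nt in enumerate(ALPHABET):
        lines.append(nt + "  " + "  ".join(f"{v:.6g}" for v in m[:, i]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_pwm_directory(path: str | Path, pseudocount: float = 0.5) -> dict[str, Pwm]:
    """A directory of PWM files constitutes a factor catalogue."""
    catalogue = {}
    for f in sorted(Path(path).iterdir()):
        if f.suffix in (".pwm", ".pfm", ".txt", ".jaspar"):
            pwm = read_pwm_file(f, pseudocount)
            if pwm.factor_name in catalogue:
                raise ValueError(f"duplicate factor {pwm.factor_name!r} in {path}")
            catalogue[pwm.factor_name] = pwm
    if not catalogue:
        raise ValueError(f"no PWM files found in {path}")
    return catalogue
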