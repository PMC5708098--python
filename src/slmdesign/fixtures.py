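"""Synthetic data generation: TF atlases, per-nucleus tables, random DNA,
and a self-contained synthetic reference bundle.

Everything here is generated, not measured.  The atlas emulates smooth
blastoderm gradients on the modelled 35.5-92.5% embryo-length window
(anterior exponential gradient, sigmoid boundary, Gaussian domes, uniform
levels); per-nucleus tables emulate reporter FISH data with per-embryo
multiplicative scale variation and per-nucleus mRNA counts drawn from the
two-state promoter model; the PWM catalogue is built from field-standard
consensus motifs of the blastoderm factors.  The *synthetic reference
bundle* stands in for the study's reference objects, which are not
distributed with this package: a 480 bp stripe-2-like element with planted
activator/repressor sites, edit targets at exactly 251 and 272 Levenshtein
edits from it (the second shrinking the element to 319 bp), sampled path
intermediates, a 40-record construct catalogue, and an averaged-expression
table whose amplitudes encode the reported qualitative outcomes (a >10-fold
peak ratio between the strong short element and the reference element).
All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .motifs import Background, Pwm, reverse_complement
from .paths import EditScript, levenshtein_script
from .profiles import DEFAULT_AP_GRID, ExpressionProfile, TfProfile
from .variability import TelegraphParams, telegraph_pmf

__all__ = [
    "SYNTHETIC_CONSENSUS",
    "make_pwm_catalogue",
    "DEFAULT_ATLAS_SPEC",
    "make_atlas",
    "random_sequence",
    "make_embryos",
    "SyntheticBundle",
    "build_reference_bundle",
    "write_bundle",
]

ALPHABET = "ACGT"

# Field-standard consensus motifs for the modelled blastoderm factors.
# The derived count matrices are synthetic (sharp consensus columns), not
# the matrices used in any published fit.
SYNTHETIC_CONSENSUS: dict[str, str] = {
    "bcd": "TAATCC",
    "hb": "ATAAAAAA",
    "Kr": "TAACCTTTC",
    "gt": "TTACGCAAT",
    "zld": "CAGGTAG",
    "Dst": "TTCCCGGAA",
    "kni": "AACTAGAC",
    "cic": "TGAATGAA",
    "Dic": "AACAATG",
}


def make_pwm_catalogue(
    factors: list[str] | None = None,
    consensus_count: float = 97.0,
    total_count: float = 100.0,
    pseudocount: float = 0.5,
) -> dict[str, Pwm]:
    """Synthetic PWMs: each column gives ``consensus_count`` of
    ``total_count`` counts to the consensus base, the rest split evenly."""
    factors = factors or list(SYNTHETIC_CONSENSUS)
    catalogue = {}
    other = (total_count - consensus_count) / 3.0
    for f in factors:
        cons = SYNTHETIC_CONSENSUS[f]
        counts = np.full((len(cons), 4), other)
        for j, ch in enumerate(cons):
            counts[j, ALPHABET.index(ch)] = consensus_count
        catalogue[f] = Pwm.from_counts(f, counts, pseudocount)
    return catalogue


# -- atlas ----------------------------------------------------------------

# Stylised AP shapes: an anterior Bicoid exponential, an anterior Hunchback
# sigmoid, anterior+posterior Giant domes, a central Kruppel dome, uniform
# Zelda, a broad central Stat92E plateau, and uniform Capicua/Dichaete.
DEFAULT_ATLAS_SPEC: dict[str, dict] = {
    "bcd": {"kind": "exponential", "amplitude": 100.0, "origin": 35.5, "length_scale": 12.0},
    "hb": {"kind": "sigmoid", "amplitude": 90.0, "midpoint": 47.0, "width": 3.0},
    "gt": {"kind": "gaussians", "components": [
        {"amplitude": 80.0, "center": 34.0, "sigma": 4.0},
        {"amplitude": 60.0, "center": 78.0, "sigma": 6.0},
    ]},
    "Kr": {"kind": "gaussians", "components": [
        {"amplitude": 90.0, "center": 52.0, "sigma": 6.0},
    ]},
    "kni": {"kind": "gaussians", "components": [
        {"amplitude": 80.0, "center": 64.0, "sigma": 5.0},
    ]},
    "zld": {"kind": "uniform", "level": 100.0},
    "Dst": {"kind": "plateau", "amplitude": 80.0, "rise": 45.0, "fall": 85.0, "width": 3.0},
    "cic": {"kind": "uniform", "level": 60.0},
    "Dic": {"kind": "uniform", "level": 50.0},
}


def _shape(grid: np.ndarray, spec: dict) -> np.ndarray:
    kind = spec["kind"]
    if kind == "exponential":
        return spec["amplitude"] * np.exp(-(grid - spec["origin"]) / spec["length_scale"])
    if kind == "sigmoid":
        return spec["amplitude"] / (1.0 + np.exp((grid - spec["midpoint"]) / spec["width"]))
    if kind == "gaussians":
        out = np.zeros_like(grid)
        for c in spec["components"]:
            out += c["amplitude"] * np.exp(-(((grid - c["center"]) / c["sigma"]) ** 2))
        return out
    if kind == "plateau":
        w = spec["width"]
        return (
            spec["amplitude"]
            / (1.0 + np.exp(-(grid - spec["rise"]) / w))
            / (1.0 + np.exp((grid - spec["fall"]) / w))
        )
    if kind == "uniform":
        return np.full_like(grid, spec["level"])
    raise ValueError(f"unknown atlas shape kind {kind!r}")


def make_atlas(
    spec: dict[str, dict] | None = None,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[TfProfile]:
    """Deterministic synthetic TF atlas; optional multiplicative lognormal
    noise with standard deviation ``noise_sd`` (log scale)."""
    spec = spec or DEFAULT_ATLAS_SPEC
    grid = DEFAULT_AP_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    atlas = []
    for factor, shape_spec in spec.items():
        conc = _shape(grid, shape_spec)
        if noise_sd > 0:
            conc = conc * rng.lognormal(0.0, noise_sd, size=grid.size)
        atlas.append(TfProfile(factor, grid, conc))
    return atlas


# -- sequences ------------------------------------------------------------


def random_sequence(
    length: int, bg: Background | None = None, seed: int | np.random.Generator = 0
) -> str:
    """i.i.d. draws from the background composition; reproducible by seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    bg = bg or Background()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return "".join(rng.choice(list(ALPHABET), size=length, p=bg.array))


def _plant(seq: list[str], pos: int, motif: str, strand: str = "+") -> None:
    if strand == "-":
        motif = reverse_complement(motif)
    seq[pos : pos + len(motif)] = list(motif)


# -- per-nucleus tables ---------------------------------------------------


def make_embryos(
    line: str,
    profile: ExpressionProfile,
    telegraph: TelegraphParams,
    n_embryos: int = 6,
    nuclei_per_bin: int = 20,
    embryo_scale_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-nucleus fluorescence table.

    Each nucleus draws an mRNA count from the telegraph distribution, scaled
    so the bin mean tracks the supplied profile, then multiplied by a
    per-embryo lognormal scale factor (sd on the log scale).
    """
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    rng = np.random.default_rng(seed)
    n_max = max(int(np.ceil(5 * telegraph.N)), 30)
    dist = telegraph_pmf(telegraph, n_max)
    counts_support = dist.n
    pmf = dist.phi / dist.phi.sum()
    mean_count = telegraph.mean

    rows = []
    nucleus = 0
    for e in range(n_embryos):
        scale = float(np.exp(rng.normal(0.0, embryo_scale_sd))) if embryo_scale_sd > 0 else 1.0
        embryo_id = f"{line}_emb{e:02d}"
        for k, ap_center in enumerate(profile.grid):
            target_mean = profile.values[k]
            for _ in range(nuclei_per_bin):
                count = rng.choice(counts_support, p=pmf)
                fluor = scale * target_mean * count / mean_count
                rows.append({
                    "embryo": embryo_id,
                    "nucleus": f"n{nucleus:06d}",
                    "ap_percent": float(ap_center + rng.uniform(-0.5, 0.5)),
                    "fluorescence": float(fluor),
                    "line": line,
                })
                nucleus += 1
    return pd.DataFrame(rows)


# -- the synthetic reference bundle --------------------------------------

# (factor, 0-based start, strand) of the sites planted in the synthetic
# 480 bp reference element: activators anterior-style (Bicoid pairs in
# head-to-head orientation, Hunchback near Bicoid) with Giant and Kruppel
# repressor sites interleaved.
_REFERENCE_LAYOUT: tuple[tuple[str, int, str], ...] = (
    ("bcd", 30, "+"), ("hb", 42, "+"), ("gt", 66, "+"),
    ("bcd", 92, "-"), ("hb", 104, "+"), ("Kr", 122, "+"),
    ("bcd", 150, "+"), ("bcd", 162, "-"), ("Kr", 183, "+"),
    ("gt", 205, "-"), ("Kr", 243, "-"), ("bcd", 261, "+"),
    ("hb", 272, "+"), ("Kr", 296, "+"), ("bcd", 318, "-"),
    ("gt", 352, "+"), ("Kr", 385, "+"), ("Kr", 432, "-"),
    ("kni", 137, "+"), ("kni", 220, "-"), ("kni", 308, "+"), ("kni", 400, "+"),
)

REFERENCE_LENGTH = 480
E_TARGET_EDITS = 251       # substitution-only design target
S_TARGET_DELETIONS = 161   # 480 -> 319 bp
S_TARGET_SUBSTITUTIONS = 111
S_SHORT_STEP = 250         # the strong short element sits 250 edits along
E_SERIES_STEPS = (24, 36, 48, 60, 72, 96, 120, 144, 168, 192, 216, 228, 240, 248, 251)
S_SERIES_STEPS = (25, 50, 75, 100, 125, 150, 175, 200, 225, 250, 272)


@dataclass(frozen=True)
class SyntheticBundle:
    """Synthetic stand-in for the study's reference data (not real data)."""

    seed: int
    catalogue: dict[str, Pwm] = field(repr=False)
    atlas: list[TfProfile] = field(repr=False)
    reference: str = field(repr=False)            # the 480 bp element
    e_script: EditScript = field(repr=False)      # reference -> e-target (251 LE)
    s_script: EditScript = field(repr=False)      # reference -> s-target (272 LE)
    s_order: tuple[int, ...] = field(repr=False)  # s-path edit order
    constructs: dict[str, str] = field(repr=False)  # the 40-record catalogue
    expression: dict[str, ExpressionProfile] = field(repr=False)

    @property
    def e_target(self) -> str:
        return self.e_script.target

    @property
    def s_target(self) -> str:
        return self.s_script.target

    def e_step(self, k: int) -> str:
        """Sequence after the first k edits of the e-path (left-to-right order)."""
        return self.e_script.apply(range(k))

    def s_step(self, k: int) -> str:
        """Sequence after the first k edits of the s-path order."""
        return self.s_script.apply(self.s_order[:k])


def _make_reference(rng: np.random.Generator, bg: Background) -> str:
    seq = list(random_sequence(REFERENCE_LENGTH, bg, rng))
    for factor, pos, strand in _REFERENCE_LAYOUT:
        _plant(seq, pos, SYNTHETIC_CONSENSUS[factor], strand)
    return "".join(seq)


def _substitute(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    out = list(seq)
    for p in positions:
        choices = [c for c in ALPHABET if c != out[p]]
        out[p] = choices[int(rng.integers(3))]
    return "".join(out)


def _edit_distance(a: str, b: str) -> int:
    """Plain edit distance, via edlib (kept independent of the package's own
    scripted Levenshtein implementation)."""
    import edlib

    return int(edlib.align(a, b)["editDistance"])


def _grow_target(
    rng: np.random.Generator,
    reference: str,
    total_edits: int,
    final_length: int,
    start: str | None = None,
    max_tries: int = 100_000,
) -> str:
    """Construct a target at *exactly* ``total_edits`` Levenshtein edits from
    the reference, with the requested final length.

    The target grows one edit at a time: a random substitution, insertion or
    deletion is proposed on the current sequence and accepted only if it
    raises the edit distance to the reference by exactly 1 (a single edit can
    never raise it by more).  Deletions/insertions are steered so the length
    lands on ``final_length`` when the distance reaches ``total_edits``.
    Substitutions alone cannot exceed the ~0.52n random-string plateau, so a
    few indels are part of any deeply diverged target, as in real sequence
    divergence.
    """
    current = start if start is not None else reference
    d = _edit_distance(reference, current)
    tries = 0
    # Substitutions toward bases under-represented in the reference push the
    # distance past the random-composition plateau (deeply diverged designed
    # sequences are composition-skewed relative to their ancestor).
    ref_freq = np.array([reference.count(c) for c in ALPHABET], dtype=float)
    ref_freq = (ref_freq + 1.0) / (ref_freq.sum() + 4.0)
    sub_weights = (1.0 / ref_freq) ** 2
    sub_weights /= sub_weights.sum()
    while d < total_edits:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not construct an exact-distance target")
        remaining = total_edits - d
        net_needed = len(current) - final_length
        if abs(net_needed) > remaining:  # unreachable; should not happen
            raise RuntimeError("length bookkeeping error in target construction")
        # propose: steer indel probability toward the needed net length change
        p_del = max(0.0, net_needed / remaining) if remaining else 0.0
        p_ins = max(0.0, -net_needed / remaining) if remaining else 0.0
        u = rng.random()
        if u < p_del:
            pos = int(rng.integers(len(current)))
            candidate = current[:pos] + current[pos + 1 :]
        elif u < p_del + p_ins:
            pos = int(rng.integers(len(current) + 1))
            base = ALPHABET[int(rng.choice(4, p=sub_weights))]
            candidate = current[:pos] + base + current[pos:]
        else:
            pos = int(rng.integers(len(current)))
            base = ALPHABET[int(rng.choice(4, p=sub_weights))]
            if base == current[pos]:
                continue
            candidate = current[:pos] + base + current[pos + 1 :]
        nd = _edit_distance(reference, candidate)
        if nd == d + 1 and abs(len(candidate) - final_length) <= total_edits - nd:
            current, d = candidate, nd
    if len(current) != final_length:
        raise RuntimeError("target construction missed the requested length")
    return current


def _attempt(build, rng: np.random.Generator, attempts: int = 8):
    last: Exception | None = None
    for _ in range(attempts):
        try:
            return build(rng)
        except RuntimeError as exc:  # restart with the advanced rng stream
            last = exc
    raise RuntimeError(f"target construction failed after {attempts} attempts: {last}")


def _make_e_target(rng: np.random.Generator, reference: str) -> EditScript:
    """A same-length design target at exactly E_TARGET_EDITS edits."""

    def build(r: np.random.Generator) -> EditScript:
        target = _grow_target(r, reference, E_TARGET_EDITS, len(reference))
        script = levenshtein_script(reference, target)
        if script.distance != E_TARGET_EDITS:
            raise RuntimeError("scripted distance disagrees with construction")
        return script

    return _attempt(build, rng)


def _make_s_target(rng: np.random.Generator, reference: str) -> EditScript:
    """A shortened (319 bp) target at exactly 272 edits: the element first
    shrinks by 161 accepted deletions, then diverges by 111 substitutions."""
    k = S_TARGET_DELETIONS + S_TARGET_SUBSTITUTIONS
    final_length = len(reference) - S_TARGET_DELETIONS

    def build(r: np.random.Generator) -> EditScript:
        shrunk = _grow_target(r, reference, S_TARGET_DELETIONS, final_length)
        target = _grow_target(r, reference, k, final_length, start=shrunk)
        script = levenshtein_script(reference, target)
        if script.distance != k:
            raise RuntimeError("scripted distance disagrees with construction")
        return script

    return _attempt(build, rng)


def _s_path_order(script: EditScript) -> tuple[int, ...]:
    """Deterministic s-path order: all deletions (and most substitutions)
    first in column order, the last 22 edits substitutions-only, so the
    step-250 intermediate already has the final 319 bp length."""
    subs = [i for i, e in enumerate(script.edits) if e.kind == "substitution"]
    non_subs = [i for i, e in enumerate(script.edits) if e.kind != "substitution"]
    tail = subs[-(script.distance - S_SHORT_STEP):]
    head = sorted(set(range(script.distance)) - set(tail))
    return tuple(head + tail)


def _homotypic(rng: np.random.Generator, bg: Background, factor: str,
               copies: int = 6, spacer: int = 24) -> str:
    motif = SYNTHETIC_CONSENSUS[factor]
    parts = [random_sequence(spacer, bg, rng)]
    for _ in range(copies):
        parts.append(motif)
        parts.append(random_sequence(spacer, bg, rng))
    return "".join(parts)


def _stripe(grid: np.ndarray, center: float, sigma: float, amplitude: float,
            baseline: float = 0.5) -> np.ndarray:
    return baseline + amplitude * np.exp(-(((grid - center) / sigma) ** 2))


def _synthetic_expression(grid: np.ndarray) -> dict[str, ExpressionProfile]:
    """Averaged-expression table emulating the reported measurements: the
    path intermediates drive stripes brighter than the reference, the short
    strong element drives >10x the reference peak, the homotypic lines
    drive broad (zld6x) or central (dst6x) patterns."""
    shapes = {
        "mse2like": _stripe(grid, 40.5, 2.5, 20.0),
        "e24": _stripe(grid, 40.5, 2.5, 35.0),
        "e36": _stripe(grid, 40.5, 2.6, 40.0),
        "e48": _stripe(grid, 40.5, 2.4, 45.0),
        "e60": _stripe(grid, 40.5, 2.5, 50.0),
        "s100": _stripe(grid, 40.5, 2.3, 15.0),
        "s250": _stripe(grid, 40.5, 2.5, 245.0),
        "zld6x": np.full_like(grid, 60.0),
        "dst6x": _shape(grid, {"kind": "plateau", "amplitude": 120.0,
                               "rise": 45.0, "fall": 85.0, "width": 3.0}),
    }
    return {name: ExpressionProfile(name, grid, v) for name, v in shapes.items()}


def build_reference_bundle(seed: int = 0) -> SyntheticBundle:
    """Build the synthetic reference bundle (pure function of the seed)."""
    rng = np.random.default_rng(seed)
    bg = Background()
    catalogue = make_pwm_catalogue()
    atlas = make_atlas(seed=seed)
    reference = _make_reference(rng, bg)
    e_script = _make_e_target(rng, reference)
    s_script = _make_s_target(rng, reference)
    s_order = _s_path_order(s_script)

    constructs: dict[str, str] = {}
    for k in E_SERIES_STEPS:
        constructs[f"e{k}"] = e_script.apply(range(k))
    for k in S_SERIES_STEPS:
        constructs[f"s{k}"] = s_script.apply(s_order[:k])

    for factor, name in (("zld", "zld6x"), ("Dst", "dst6x"), ("bcd", "bcd6x"),
                         ("hb", "hb6x"), ("Dic", "dic6x")):
        constructs[name] = _homotypic(rng, bg, factor)

    s272 = constructs["s272"]
    # repressor-deletion variants: replace each repressor consensus match
    # with random background sequence
    def strip_motifs(seq: str, factors: tuple[str, ...]) -> str:
        out = seq
        for f in factors:
            for m in (SYNTHETIC_CONSENSUS[f], reverse_complement(SYNTHETIC_CONSENSUS[f])):
                while m in out:
                    out = out.replace(m, random_sequence(len(m), bg, rng), 1)
        return out

    constructs["s272_dgt_dkr"] = strip_motifs(s272, ("gt", "Kr"))
    constructs["s272_dgt"] = strip_motifs(s272, ("gt",))
    constructs["s272_dkr"] = strip_motifs(s272, ("Kr",))

    # orientation variant: flip the reference's first head-to-head Bicoid pair
    flipped = list(reference)
    L = len(SYNTHETIC_CONSENSUS["bcd"])
    for pos in (150, 162):
        window = reference[pos : pos + L]
        _plant(flipped, pos, reverse_complement(window))
    constructs["mse2like_bcd_flipped"] = "".join(flipped)

    # partial-revert variants along the paths (restore the last edits)
    constructs["e72_hb_restored"] = e_script.apply(range(71))
    constructs["e72_hbbcd_restored"] = e_script.apply(range(70))
    constructs["e72_dcic"] = _substitute(rng, e_script.apply(range(72)),
                                         np.array([5]))
    constructs["s250_ddic"] = strip_motifs(constructs["s250"], ("Dic",))
    s250 = constructs["s250"]
    constructs["s250_bcdhb_revert"] = _substitute(
        rng, s250, rng.choice(len(s250), size=15, replace=False)
    )

    assert len(constructs) == 40, f"expected 40 constructs, built {len(constructs)}"

    expression = _synthetic_expression(DEFAULT_AP_GRID.copy())
    return SyntheticBundle(
        seed=seed,
        catalogue=catalogue,
        atlas=atlas,
        reference=reference,
        e_script=e_script,
        s_script=s_script,
        s_order=s_order,
        constructs=constructs,
        expression=expression,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write the bundle as FASTA / PWM / TSV files."""
    from . import io as sio
    from .motifs import write_pwm_file

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "pwms").mkdir(exist_ok=True)
    for name, pwm in bundle.catalogue.items():
        write_pwm_file(pwm, outdir / "pwms" / f"{name}.pwm", counts_scale=100.0)
    sio.write_fasta({"mse2like": bundle.reference}, outdir / "reference.fa")
    sio.write_fasta(bundle.constructs, outdir / "constructs.fa")
    sio.write_atlas(bundle.atlas, outdir / "atlas.tsv", seed=bundle.seed)
    sio.write_expression_table(bundle.expression, outdir / "expression.tsv",
                               seed=bundle.seed)
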