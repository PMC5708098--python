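"""Thermodynamic sequence-level model of enhancer-driven expression.

The model treats the enhancer as a set of annotated binding sites competing
for occupancy at thermodynamic equilibrium.  A bound site carries the
statistical weight

    w = K_factor * [TF] * e^LLR ,

and a configuration (any subset of sites whose footprints do not overlap —
steric competition) has weight equal to the product of its site weights
times a cooperativity bonus for each consecutively bound pair covered by a
cooperativity rule within its gap limit.  Marginal per-site occupancies are
obtained from the partition function over all configurations, computed
exactly by a forward/backward dynamic programme over sites in position
order (linear chain with nearest-bound-neighbour interactions).

Occupancies are converted to transcription by the documented rule set:
activators contribute their activation strength times occupancy; a
coactivatable repressor (Hunchback) contributes as an activator when bound
near a bound coactivating partner (Bicoid), otherwise as a repressor;
short-range repressors quench nearby activator contributions
multiplicatively (survival factor 1 - q * occupancy per repressor) and may
additionally repress the basal machinery directly.  Net activation is
passed through a saturating logistic response scaled to R_max and clipped
to the 0-255 display scale.

Expression is computed independently for each AP bin from that bin's TF
concentrations, matching the per-nucleus framing of blastoderm data.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping

import numpy as np

from .motifs import Background, BindingSite, Pwm, scan_sequence
from .params import ParameterSet
from .profiles import ExpressionProfile, TfProfile

__all__ = ["site_weights", "compute_occupancy", "annotate_sites", "predict_expression"]


def _interval_gap(a: BindingSite, b: BindingSite) -> int:
    """Distance in bp between two footprints (0 when they touch or overlap)."""
    return max(0, a.start - b.end, b.start - a.end)


def _coop_strength(left: BindingSite, right: BindingSite, params: ParameterSet) -> float:
    """Cooperativity bonus for a consecutively bound pair, 1.0 if none applies."""
    gap = right.start - left.end
    for site, other in ((right, left), (left, right)):
        rule = params.factors[site.factor_name].cooperativity
        if rule and rule.partner == other.factor_name and 0 <= gap <= rule.max_gap:
            return rule.strength
    return 1.0


def site_weights(
    sites: list[BindingSite],
    concentrations: Mapping[str, float],
    params: ParameterSet,
) -> np.ndarray:
    w = np.empty(len(sites))
    for i, s in enumerate(sites):
        if s.factor_name not in params.factors:
            raise ValueError(f"no TF parameters for factor {s.factor_name!r}")
        conc = concentrations.get(s.factor_name)
        if conc is None:
            raise ValueError(f"no concentration given for factor {s.factor_name!r}")
        if conc < 0:
            raise ValueError(f"negative concentration for {s.factor_name!r}")
        w[i] = params.factors[s.factor_name].binding_scale * conc * math.exp(s.llr)
    return w


def compute_occupancy(
    sites: list[BindingSite],
    concentrations: Mapping[str, float],
    params: ParameterSet,
) -> np.ndarray:
    """Marginal probability that each site is bound, in [0, 1].

    Exact for the configuration model described in the module docstring;
    agrees with brute-force enumeration over all 2^n configurations.
    """
    n = len(sites)
    if n == 0:
        return np.zeros(0)
    starts = [s.start for s in sites]
    if any(starts[i] > starts[i + 1] for i in range(n - 1)):
        raise ValueError("sites must be sorted by start position")
    w = site_weights(sites, concentrations, params)

    # forward: f[i] = total weight of configurations of sites[0..i] with i bound
    f = np.empty(n)
    for i in range(n):
        acc = 1.0
        for j in range(i):
            if sites[j].end <= sites[i].start:
                acc += f[j] * _coop_strength(sites[j], sites[i], params)
        f[i] = w[i] * acc
    z = 1.0 + f.sum()

    # backward: h[i] = 1 + sum_{j after i} coop(i,j) * w[j] * h[j]
    h = np.empty(n)
    for i in range(n - 1, -1, -1):
        acc = 1.0
        for j in range(i + 1, n):
            if sites[j].start >= sites[i].end:
                acc += _coop_strength(sites[i], sites[j], params) * w[j] * h[j]
        h[i] = acc

    occ = f * h / z
    return np.clip(occ, 0.0, 1.0)


def annotate_sites(
    seq: str,
    catalogue: Mapping[str, Pwm],
    params: ParameterSet,
    bg: Background | None = None,
    threshold: float = 0.0,
) -> list[BindingSite]:
    """All sites (LLR > threshold, both strands) for the factors of a set."""
    bg = bg or Background()
    sites: list[BindingSite] = []
    for factor in params.factors:
        if factor not in catalogue:
            raise ValueError(
                f"factor {factor!r} has TF parameters but no PWM in the catalogue"
            )
        sites.extend(scan_sequence(seq, catalogue[factor], bg, threshold))
    sites.sort(key=lambda s: (s.start, s.end, s.strand, s.factor_name))
    return sites


def _coactivation_prob(
    i: int, sites: list[BindingSite], occ: np.ndarray, params: ParameterSet
) -> float:
    """Probability that site i's coactivatable repressor is switched to an
    activator by at least one bound partner within range (independent
    approximation over partner sites)."""
    rule = params.factors[sites[i].factor_name].coactivation
    if rule is None:
        return 0.0
    p_none = 1.0
    for j, other in enumerate(sites):
        if j == i or other.factor_name not in rule.partners:
            continue
        if _interval_gap(sites[i], other) <= rule.range:
            p_none *= 1.0 - occ[j]
    return 1.0 - p_none


def _bin_expression(
    sites: list[BindingSite],
    concentrations: Mapping[str, float],
    params: ParameterSet,
) -> float:
    occ = compute_occupancy(sites, concentrations, params)
    n = len(sites)
    coact = np.array([_coactivation_prob(i, sites, occ, params) for i in range(n)])

    # effective activator / repressor occupancy per site
    act_contrib = np.zeros(n)      # pre-quench activation contribution
    rep_occ = np.zeros(n)          # occupancy acting in repressor mode
    for i, s in enumerate(sites):
        tf = params.factors[s.factor_name]
        if tf.role == "activator":
            act_contrib[i] = tf.activation_strength * occ[i]
        elif tf.role == "repressor":
            rep_occ[i] = occ[i]
        else:  # coactivatable-repressor
            act_contrib[i] = tf.activation_strength * occ[i] * coact[i]
            rep_occ[i] = occ[i] * (1.0 - coact[i])

    activation = 0.0
    direct_repression = 0.0
    for i, s in enumerate(sites):
        if act_contrib[i] > 0.0:
            survival = 1.0
            for j, r in enumerate(sites):
                if j == i or rep_occ[j] == 0.0:
                    continue
                tf_r = params.factors[r.factor_name]
                if tf_r.quench_efficiency > 0.0 and _interval_gap(s, r) <= tf_r.quench_range:
                    survival *= 1.0 - tf_r.quench_efficiency * rep_occ[j]
            activation += act_contrib[i] * survival
    for j, r in enumerate(sites):
        if rep_occ[j] > 0.0:
            direct_repression += (
                params.factors[r.factor_name].direct_repression_strength * rep_occ[j]
            )

    net = activation - direct_repression
    g = 1.0 / (1.0 + math.exp(-params.response_steepness * (net - params.response_midpoint)))
    return float(np.clip(params.r_max * g, 0.0, 255.0))


def predict_expression(
    seq: str,
    atlas: Iterable[TfProfile],
    params: ParameterSet,
    catalogue: Mapping[str, Pwm],
    bg: Background | None = None,
    name: str = "model",
    threshold: float = 0.0,
) -> ExpressionProfile:
    """Predicted expression profile of a sequence along the AP axis."""
    profiles = {p.factor_name: p for p in atlas}
    grids = [p.grid for p in profiles.values()]
    if not grids:
        raise ValueError("atlas is empty")
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise ValueError("atlas factors are on mismatched AP grids")
    grid = grids[0]

    for factor in params.factors:
        if factor not in profiles and factor not in params.uniform_factors:
            raise ValueError(
                f"factor {factor!r} has neither an atlas profile nor a uniform level"
            )

    sites = annotate_sites(seq, catalogue, params, bg, threshold)
    values = np.empty(grid.size)
    for k in range(grid.size):
        conc = {
            factor: (
                params.uniform_factors[factor]
                if factor in params.uniform_factors
                else profiles[factor].concentrations[k]
            )
            for factor in params.factors
        }
        values[k] = _bin_expression(sites, conc, params)
    return ExpressionProfile(name, grid, values)
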