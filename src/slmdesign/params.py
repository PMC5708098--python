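"""Kinetic parameter sets for the thermodynamic sequence-level model.

A parameter set bundles, for every transcription factor it knows about, the
quantities that convert binding-site annotation into regulatory output:

* ``binding_scale`` (K) — converts concentration x affinity (e^LLR) into the
  statistical weight of a bound site;
* a ``role`` — activator, repressor, or coactivatable-repressor (a repressor
  that acts as an activator when bound near a coactivating partner, the rule
  used for Hunchback near Bicoid or Caudal);
* ``activation_strength`` for activators, ``quench_efficiency`` /
  ``quench_range`` for short-range repressors, ``direct_repression_strength``
  for repression of the basal machinery;
* optional pairwise ``cooperativity`` (partner, strength >= 1, max_gap) and
  ``coactivation`` (partners, range) rules;

plus global transcription parameters: the maximum output ``R_max`` on the
0-255 display scale and the midpoint/steepness of the saturating response.

Seven sets, ids 1-7, are shipped as a YAML config.  The shipped values are
synthetic defaults authored for this package (they span the documented model
vocabulary; they are not a trained fit).  Set 7 additionally declares Zelda
as a uniformly expressed activator at a constant concentration of 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

ROLES = ("activator", "repressor", "coactivatable-repressor")

__all__ = ["TfParams", "ParameterSet", "load_parameter_set", "load_all_parameter_sets",
           "default_config_path", "save_parameter_sets"]


@dataclass(frozen=True)
class Cooperativity:
    partner: str
    strength: float
    max_gap: int

    def __post_init__(self) -> None:
        if self.strength < 1:
            raise ValueError("cooperativity strength must be >= 1")
        if self.max_gap < 0:
            raise ValueError("cooperativity max_gap must be >= 0")


@dataclass(frozen=True)
class Coactivation:
    partners: tuple[str, ...]
    range: int

    def __post_init__(self) -> None:
        if self.range <= 0:
            raise ValueError("coactivation range must be positive")


@dataclass(frozen=True)
class TfParams:
    factor_name: str
    binding_scale: float
    role: str
    activation_strength: float = 0.0
    quench_efficiency: float = 0.0
    quench_range: int = 100
    direct_repression_strength: float = 0.0
    cooperativity: Cooperativity | None = None
    coactivation: Coactivation | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.binding_scale <= 0:
            raise ValueError("binding_scale must be positive")
        if not 0.0 <= self.quench_efficiency <= 1.0:
            raise ValueError("quench_efficiency must lie in [0, 1]")
        if self.quench_range <= 0:
            raise ValueError("quench_range must be positive")
        if self.activation_strength < 0 or self.direct_repression_strength < 0:
            raise ValueError("strengths must be nonnegative")


@dataclass(frozen=True)
class ParameterSet:
    id: int
    factors: dict[str, TfParams]
    r_max: float = 255.0
    response_midpoint: float = 3.0
    response_steepness: float = 1.5
    uniform_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.id <= 7:
            raise ValueError(f"parameter-set id must be 1-7, got {self.id}")
        if self.r_max <= 0:
            raise ValueError("R_max must be positive")
        for tf in self.factors.values():
            if tf.cooperativity and tf.cooperativity.partner not in self.factors:
                raise ValueError(
                    f"{tf.factor_name}: cooperativity partner "
                    f"{tf.cooperativity.partner!r} has no parameters in set {self.id}"
                )
            if tf.coactivation:
                for p in tf.coactivation.partners:
                    if p not in self.factors:
                        raise ValueError(
                            f"{tf.factor_name}: coactivation partner {p!r} has no "
                            f"parameters in set {self.id}"
                        )
        for name in self.uniform_factors:
            if name not in self.factors:
                raise ValueError(f"uniform factor {name!r} has no TF parameters")


_TF_KEYS = {"binding_scale", "role", "activation_strength", "quench_efficiency",
            "quench_range", "direct_repression_strength", "cooperativity",
            "coactivation"}
_SET_KEYS = {"factors", "r_max", "response_midpoint", "response_steepness",
             "uniform_factors"}


def _tf_from_dict(name: str, raw: dict) -> TfParams:
    unknown = set(raw) - _TF_KEYS
    if unknown:
        raise ValueError(f"factor {name!r}: unknown keys {sorted(unknown)}")
    if "binding_scale" not in raw or "role" not in raw:
        raise ValueError(f"factor {name!r}: binding_scale and role are required")
    coop = raw.get("cooperativity")
    coact = raw.get("coactivation")
    return TfParams(
        factor_name=name,
        binding_scale=float(raw["binding_scale"]),
        role=raw["role"],
        activation_strength=float(raw.get("activation_strength", 0.0)),
        quench_efficiency=float(raw.get("quench_efficiency", 0.0)),
        quench_range=int(raw.get("quench_range", 100)),
        direct_repression_strength=float(raw.get("direct_repression_strength", 0.0)),
        cooperativity=Cooperativity(
            coop["partner"], float(coop["strength"]), int(coop["max_gap"])
        ) if coop else None,
        coactivation=Coactivation(
            tuple(coact["partners"]), int(coact["range"])
        ) if coact else None,
    )


def _set_from_dict(set_id: int, raw: dict) -> ParameterSet:
    unknown = set(raw) - _SET_KEYS
    if unknown:
        raise ValueError(f"set {set_id}: unknown keys {sorted(unknown)}")
    factors = {name: _tf_from_dict(name, tf) for name, tf in raw["factors"].items()}
    return ParameterSet(
        id=set_id,
        factors=factors,
        r_max=float(raw.get("r_max", 255.0)),
        response_midpoint=float(raw.get("response_midpoint", 3.0)),
        response_steepness=float(raw.get("response_steepness", 1.5)),
        uniform_factors={k: float(v) for k, v in raw.get("uniform_factors", {}).items()},
    )


def default_config_path() -> Path:
    return Path(resources.files("slmdesign").joinpath("data/parameter_sets.yaml"))


def load_parameter_set(source: str | Path | None = None, id: int = 1) -> ParameterSet:
    """Load one parameter set (id 1-7) from a YAML config.

    With ``source=None`` the packaged synthetic defaults are used.
    """
    if not 1 <= id <= 7:
        raise ValueError(f"parameter-set id must be 1-7, got {id}")
    sets = load_all_parameter_sets(source)
    if id not in sets:
        raise ValueError(f"config defines sets {sorted(sets)}; id {id} missing")
    return sets[id]


def load_all_parameter_sets(source: str | Path | None = None) -> dict[int, ParameterSet]:
    path = Path(source) if source else default_config_path()
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "parameter_sets" not in raw:
        raise ValueError(f"{path}: expected a top-level 'parameter_sets' mapping")
    return {
        int(set_id): _set_from_dict(int(set_id), body)
        for set_id, body in raw["parameter_sets"].items()
    }


def save_parameter_sets(sets: dict[int, ParameterSet], path: str | Path) -> None:
    """Write sets back to YAML (round-trips with the loader)."""
    out: dict = {"parameter_sets": {}}
    for set_id, ps in sorted(sets.items()):
        factors = {}
        for name, tf in ps.factors.items():
            d: dict = {"binding_scale": tf.binding_scale, "role": tf.role}
            if tf.activation_strength:
                d["activation_strength"] = tf.activation_strength
            if tf.quench_efficiency:
                d["quench_efficiency"] = tf.quench_efficiency
                d["quench_range"] = tf.quench_range
            if tf.direct_repression_strength:
                d["direct_repression_strength"] = tf.direct_repression_strength
            if tf.cooperativity:
                d["cooperativity"] = {
                    "partner": tf.cooperativity.partner,
                    "strength": tf.cooperativity.strength,
                    "max_gap": tf.cooperativity.max_gap,
                }
            if tf.coactivation:
                d["coactivation"] = {
                    "partners": list(tf.coactivation.partners),
                    "range": tf.coactivation.range,
                }
            factors[name] = d
        body: dict = {
            "factors": factors,
            "r_max": ps.r_max,
            "response_midpoint": ps.response_midpoint,
            "response_steepness": ps.response_steepness,
        }
        if ps.uniform_factors:
            body["uniform_factors"] = dict(ps.uniform_factors)
        out["parameter_sets"][set_id] = body
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
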