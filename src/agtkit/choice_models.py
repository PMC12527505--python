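"""Effort-discounting choice models for binary accept/refuse offers.

The decision value of an offer is an additive combination of an acceptance
bias (K), linear reward sensitivity (LinR), optional quadratic reward
sensitivity (R2), linear (LinE) and quadratic (E2) effort sensitivity, and
an optional reward-by-effort interaction (RxE):

    V(r, e) = K + LinR * r + R2 * r^2 + LinE * e + E2 * e^2 + RxE * r * e

with r the coded reward (apples / max apples, so 0.25 .. 1.0 on the default
grid) and e the coded effort (proportion of MVC, 0.2 .. 0.8).  The offer is
accepted with probability logistic(V).  A model specification selects which
terms are free parameters and which are clamped to constants — notably the
constrained variant with LinE fixed at -15, used when the linear and
quadratic effort terms trade off too strongly to be separately identified.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import expit, log_expit

__all__ = [
    "ModelError",
    "DataError",
    "TERMS",
    "Offer",
    "OfferCoding",
    "ParamVector",
    "ModelSpec",
    "FamilyConfig",
    "decision_value",
    "accept_probability",
    "log_likelihood",
    "enumerate_model_family",
    "pilot_winning_spec",
    "constrained_winning_spec",
]

#: All value-function terms, in canonical order.
TERMS: Tuple[str, ...] = ("K", "LinR", "R2", "LinE", "E2", "RxE")


class ModelError(ValueError):
    """Model specification and parameter mismatch."""


class DataError(ValueError):
    """Trial data outside the model's coding domain."""


@dataclass(frozen=True)
class Offer:
    """A single offer: ``reward_apples`` apples for ``effort_prop`` of MVC."""

    reward_apples: float
    effort_prop: float

    def __post_init__(self):
        if self.reward_apples <= 0:
            raise DataError("reward must be positive")
        if not (0 < self.effort_prop <= 1):
            raise DataError("effort must lie in (0, 1]")


@dataclass(frozen=True)
class OfferCoding:
    """Maps raw offers onto the model's covariate scale.

    Reward is coded as ``apples / reward_max`` (default max 12 apples, so the
    default grid codes to 0.25/0.5/0.75/1.0); effort enters directly as the
    proportion of MVC.  Both maps are strictly increasing.
    """

    reward_max: float = 12.0
    effort_scale: float = 1.0

    def __post_init__(self):
        if self.reward_max <= 0 or self.effort_scale <= 0:
            raise ModelError("coding scales must be positive")

    def code_reward(self, apples):
        return np.asarray(apples, dtype=float) / self.reward_max

    def code_effort(self, effort_prop):
        return np.asarray(effort_prop, dtype=float) * self.effort_scale


def _term_basis(term: str, r, e):
    if term == "K":
        return np.ones_like(np.asarray(r, dtype=float))
    if term == "LinR":
        return r
    if term == "R2":
        return r ** 2
    if term == "LinE":
        return e
    if term == "E2":
        return e ** 2
    if term == "RxE":
        return r * e
    raise ModelError(f"unknown term {term!r}")


@dataclass(frozen=True)
class ParamVector:
    """Subject-level parameters of the four-term model.

    K is the acceptance bias (logit units; higher = more likely to accept),
    LinR the linear reward sensitivity (more positive = greater subjective
    reward), LinE the linear effort sensitivity (more negative = greater
    subjective effort) and E2 the quadratic effort sensitivity (negative
    values make effort cost grow disproportionately at high effort).
    """

    K: float = 0.0
    LinR: float = 0.0
    LinE: float = 0.0
    E2: float = 0.0

    def as_dict(self) -> Dict[str, float]:
        return {"K": self.K, "LinR": self.LinR, "LinE": self.LinE, "E2": self.E2}


def _coef(params: Union[ParamVector, Mapping[str, float]], term: str) -> float:
    if isinstance(params, ParamVector):
        d = params.as_dict()
    else:
        d = params
    if term not in d:
        raise ModelError(f"model requires parameter {term!r} but it is absent")
    value = float(d[term])
    if not np.isfinite(value):
        raise ModelError(f"parameter {term!r} is not finite")
    return value


@dataclass(frozen=True)
class ModelSpec:
    """Which value-function terms are free, which are clamped, and the coding.

    ``free_terms`` are estimated; ``constraints`` maps a term to a fixed
    constant; any term in neither contributes zero.  The intercept-only model
    (``free_terms=("K",)``) is valid.
    """

    free_terms: Tuple[str, ...] = ("K", "LinR", "LinE", "E2")
    constraints: Mapping[str, float] = field(default_factory=dict)
    coding: OfferCoding = OfferCoding()

    def __post_init__(self):
        object.__setattr__(self, "free_terms", tuple(self.free_terms))
        object.__setattr__(self, "constraints", dict(self.constraints))
        for t in list(self.free_terms) + list(self.constraints):
            if t not in TERMS:
                raise ModelError(f"unknown term {t!r}")
        overlap = set(self.free_terms) & set(self.constraints)
        if overlap:
            raise ModelError(f"terms {sorted(overlap)} cannot be both free and constrained")
        if not self.free_terms and not self.constraints:
            raise ModelError("model must include at least one term")

    @property
    def included_terms(self) -> Tuple[str, ...]:
        return tuple(t for t in TERMS if t in self.free_terms or t in self.constraints)

    @property
    def name(self) -> str:
        free = "+".join(t for t in TERMS if t in self.free_terms)
        cons = ",".join(f"{t}={v:g}" for t, v in sorted(self.constraints.items()))
        return free + (f"|{cons}" if cons else "")

    def design_matrix(self, rewards, efforts) -> Tuple[np.ndarray, np.ndarray]:
        """Return ``(X_free, offset)`` such that ``V = theta @ X_free.T + offset``.

        ``X_free`` has one column per free term (in canonical order);
        ``offset`` accumulates the constrained terms' contributions.
        """
        r = self.coding.code_reward(rewards)
        e = self.coding.code_effort(efforts)
        cols = [
            _term_basis(t, r, e) for t in TERMS if t in self.free_terms
        ]
        X = np.column_stack(cols) if cols else np.zeros((np.size(r), 0))
        offset = np.zeros(np.shape(r))
        for t, v in self.constraints.items():
            offset = offset + v * _term_basis(t, r, e)
        return X, offset

    @property
    def free_in_order(self) -> Tuple[str, ...]:
        return tuple(t for t in TERMS if t in self.free_terms)


def pilot_winning_spec(coding: OfferCoding = OfferCoding()) -> ModelSpec:
    """The four-parameter model: free K, LinR, LinE and E2."""
    return ModelSpec(free_terms=("K", "LinR", "LinE", "E2"), coding=coding)


def constrained_winning_spec(const_e: float = -15.0,
                             coding: OfferCoding = OfferCoding()) -> ModelSpec:
    """The four-term model with the linear effort term clamped (ConstE).

    Used when LinE and E2 trade off too strongly for both to be estimated;
    LinE is fixed at the pilot-average value of -15.
    """
    return ModelSpec(free_terms=("K", "LinR", "E2"),
                     constraints={"LinE": const_e}, coding=coding)


def decision_value(params, offer: Offer, spec: ModelSpec) -> float:
    """Additive decision value of ``offer`` under ``spec``."""
    r = float(spec.coding.code_reward(offer.reward_apples))
    e = float(spec.coding.code_effort(offer.effort_prop))
    v = 0.0
    for t in spec.free_terms:
        v += _coef(params, t) * float(_term_basis(t, r, e))
    for t, c in spec.constraints.items():
        v += c * float(_term_basis(t, r, e))
    return v


def accept_probability(V) -> float:
    """Logistic choice rule: P(accept) = 1 / (1 + exp(-V))."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ModelError("decision value must be finite")
    p = expit(V)
    return float(p) if p.ndim == 0 else p


def log_likelihood(params, records: Sequence, spec: ModelSpec) -> float:
    """Bernoulli log-likelihood of observed accept/refuse decisions.

    Exertion outcomes and omission flags do not enter the likelihood:
    outcomes are deterministic and the decision precedes the omission cue.
    """
    total = 0.0
    for rec in records:
        if rec.accepted is None:
            raise DataError(f"trial {rec.trial_index} has no decision")
        if not (0 < rec.effort_prop <= 1) or rec.reward_apples <= 0:
            raise DataError(f"trial {rec.trial_index} outside coding domain")
        v = decision_value(params, Offer(rec.reward_apples, rec.effort_prop), spec)
        total += float(log_expit(v) if rec.accepted else log_expit(-v))
    return total


@dataclass(frozen=True)
class FamilyConfig:
    """Configuration of the candidate-model family.

    The family spans all subsets of ``optional_terms`` (the intercept K is
    always included), plus, for every spec containing a term listed in
    ``constraint_options``, a variant with that term clamped to each listed
    constant.  The four-term model and its ConstE variant are members of the
    default family.
    """

    optional_terms: Tuple[str, ...] = ("LinR", "R2", "LinE", "E2", "RxE")
    constraint_options: Mapping[str, Tuple[float, ...]] = field(
        default_factory=lambda: {"LinE": (-15.0,)}
    )
    coding: OfferCoding = OfferCoding()

    def __post_init__(self):
        object.__setattr__(self, "optional_terms", tuple(self.optional_terms))
        object.__setattr__(self, "constraint_options", dict(self.constraint_options))
        if not set(self.optional_terms) <= set(TERMS):
            raise ModelError("unknown optional terms")


def enumerate_model_family(config: FamilyConfig = FamilyConfig()) -> list:
    """Deduplicated list of candidate ModelSpecs spanned by ``config``.

    The intercept is mandatory, so the family is never empty; the
    intercept-only configuration yields exactly one spec.
    """
    bad = set(config.constraint_options) - set(config.optional_terms)
    if bad:
        raise ModelError(f"constraint options for terms not in the family: {sorted(bad)}")
    specs = {}
    for k in range(len(config.optional_terms) + 1):
        for subset in itertools.combinations(config.optional_terms, k):
            free = ("K",) + subset
            base = ModelSpec(free_terms=free, coding=config.coding)
            specs[base.name] = base
            for term, values in config.constraint_options.items():
                if term in subset:
                    for v in values:
                        variant = ModelSpec(
                            free_terms=tuple(t for t in free if t != term),
                            constraints={term: float(v)},
                            coding=config.coding,
                        )
                        specs[variant.name] = variant
    return list(specs.values())
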