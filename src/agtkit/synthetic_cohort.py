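"""Generative simulator of AGT cohorts.

Produces trial-level choice data, exertion outcomes and questionnaire
totals with the statistical structure the downstream analyses assume: a
wide between-subject spread of acceptance rates (reaching both below 40%
and exactly 100%), acceptance decreasing in effort and increasing in
reward with a reward-by-effort interaction, and case-control group
differences confined to the acceptance bias K.

Subject-level parameters are drawn from group-level normal distributions
— the generative mirror of the hierarchical model fitted downstream.  K
and E2 are given a positive correlation (less effort-sensitive subjects
also tend to accept more) so that the population, like the empirical one,
contains subjects at ceiling who accept every offer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .choice_models import (
    ModelSpec,
    ParamVector,
    constrained_winning_spec,
)
from .task_design import (
    DesignGrid,
    TrialRecord,
    TrialSchedule,
    assign_exertion_omission,
    build_schedule,
)

__all__ = [
    "SpecError",
    "GroupSpec",
    "SubjectProfile",
    "CohortData",
    "INSTRUMENTS",
    "FACTOR_NAMES",
    "default_loading_matrix",
    "default_group_specs",
    "DEFAULT_GROUP_SIZES",
    "draw_subjects",
    "simulate_choices",
    "simulate_exertion",
    "simulate_questionnaires",
    "generate_cohort",
]


class SpecError(ValueError):
    """Invalid population specification."""


#: Questionnaire instruments simulated (total scores, standardised units).
#: Multi-dimensional scales contribute their sub-scale totals (apathy scale
#: behavioural/cognitive/emotional; anticipatory and consummatory pleasure;
#: the two dysfunctional-attitudes short forms), so every latent factor has
#: at least two indicators and the factor model is identified.
INSTRUMENTS: Tuple[str, ...] = (
    "BDI", "HAMD", "LOTR", "STAI",
    "AES-B", "AES-C", "AES-E",
    "SHAPS", "TEPS-A", "TEPS-C",
    "DAS-1", "DAS-2",
)

#: Latent symptom factors, in canonical order.
FACTOR_NAMES: Tuple[str, ...] = (
    "Low-mood", "Apathy", "Hedonia", "Dysfunctional Attitudes",
)


def default_loading_matrix() -> pd.DataFrame:
    """Default instrument-by-factor loading matrix.

    Depression/anxiety scales load on Low-mood (the optimism scale LOTR
    negatively), the apathy scale on Apathy, the two pleasure scales on
    Hedonia with opposite signs (their scoring conventions run in opposite
    directions), and the dysfunctional-attitudes scale on its own factor.
    """
    L = np.zeros((len(INSTRUMENTS), 4))
    L[0, 0] = 0.85   # BDI
    L[1, 0] = 0.80   # HAM-D
    L[2, 0] = -0.70  # LOTR (optimism: loads negatively on Low-mood)
    L[3, 0] = 0.75   # STAI
    L[4, 1] = 0.80   # AES behavioural
    L[5, 1] = 0.75   # AES cognitive
    L[6, 1] = 0.70   # AES emotional
    L[7, 2] = 0.80   # SHAPS
    L[8, 2] = -0.75  # TEPS anticipatory (opposite scoring direction to SHAPS)
    L[9, 2] = -0.70  # TEPS consummatory
    L[10, 3] = 0.85  # DAS short form 1
    L[11, 3] = 0.80  # DAS short form 2
    return pd.DataFrame(L, index=list(INSTRUMENTS), columns=list(FACTOR_NAMES))


@dataclass(frozen=True)
class GroupSpec:
    """Population-level distribution for one participant group.

    ``param_means`` / ``param_sds`` give the group-level normal
    distributions of the free model parameters (on the coded-offer logit
    scale).  ``k_e2_corr`` correlates K and E2 draws.  ``age_effect_on_k``
    shifts K linearly with (age - age_mean), in logit units per year.
    Success-model parameters define P(success | effort) =
    logistic(a - b * effort).
    """

    label: str = "CTR"
    param_means: Mapping[str, float] = field(
        default_factory=lambda: {"K": 9.0, "LinR": 6.0, "E2": -8.0}
    )
    param_sds: Mapping[str, float] = field(
        default_factory=lambda: {"K": 3.0, "LinR": 4.0, "E2": 6.5}
    )
    k_e2_corr: float = 0.5
    age_mean: float = 35.0
    age_sd: float = 10.0
    age_bounds: Tuple[float, float] = (18.0, 60.0)
    age_effect_on_k: float = 0.0
    success_intercept: float = 6.0
    success_slope: float = 4.5
    mvc_mean: float = 320.0
    mvc_sd: float = 60.0
    symptom_shifts: Tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "param_means", dict(self.param_means))
        object.__setattr__(self, "param_sds", dict(self.param_sds))
        if any(s <= 0 for s in self.param_sds.values()):
            raise SpecError("parameter standard deviations must be positive")
        if set(self.param_means) != set(self.param_sds):
            raise SpecError("param_means and param_sds must name the same terms")
        if not (-1 < self.k_e2_corr < 1):
            raise SpecError("k_e2_corr must lie in (-1, 1)")
        if self.age_bounds[0] >= self.age_bounds[1]:
            raise SpecError("invalid age bounds")
        if len(self.symptom_shifts) != len(FACTOR_NAMES):
            raise SpecError("symptom_shifts must have one entry per factor")


#: Final case-control sample sizes (CTR, REL, REM, MDD).
DEFAULT_GROUP_SIZES: Dict[str, int] = {"CTR": 57, "REL": 36, "REM": 46, "MDD": 41}

# Depressed-group K deficit: 0.39 pooled-sd units below CTR/REL, the
# magnitude of the empirical remitted+current vs never-depressed contrast.
_K_GAP_SD_UNITS = 0.39


def default_group_specs(age_effect_on_k: float = 0.075) -> Dict[str, GroupSpec]:
    """Default four-group population.

    Group differences live only in the mean of K: the REM and MDD groups sit
    0.39 pooled-sd units below CTR/REL.  LinR and E2 distributions are
    identical across groups.  The default age effect induces an age-
    acceptance correlation of roughly 0.2 across the cohort.
    """
    base = GroupSpec(age_effect_on_k=age_effect_on_k)
    k_gap = _K_GAP_SD_UNITS * base.param_sds["K"]
    means_low = dict(base.param_means)
    means_low["K"] = base.param_means["K"] - k_gap
    shifts = {
        "CTR": (0.0, 0.0, 0.0, 0.0),
        "REL": (0.2, 0.1, 0.1, 0.1),
        "REM": (0.6, 0.5, 0.5, 0.4),
        "MDD": (1.5, 1.0, 1.0, 0.9),
    }
    specs = {}
    for g in ("CTR", "REL", "REM", "MDD"):
        means = base.param_means if g in ("CTR", "REL") else means_low
        specs[g] = replace(base, label=g, param_means=dict(means),
                           symptom_shifts=shifts[g])
    return specs


@dataclass
class SubjectProfile:
    """One simulated participant with their generating ('true') parameters."""

    subject_id: str
    group: str
    age: float
    params: ParamVector
    mvc: float
    factors: np.ndarray
    questionnaires: Optional[Dict[str, float]] = None
    practice_pass_high: bool = True
    success_intercept: float = 6.0
    success_slope: float = 4.5

    def __post_init__(self):
        if self.mvc <= 0:
            raise SpecError("MVC must be positive")
        vals = self.params.as_dict().values()
        if not all(np.isfinite(v) for v in vals):
            raise SpecError("parameters must be finite")


@dataclass
class CohortData:
    """Participant-level and trial-level tables for a simulated cohort."""

    participants: pd.DataFrame
    trials: pd.DataFrame

    def records_for(self, subject_id: str) -> List[TrialRecord]:
        sub = self.trials[self.trials["participant_id"] == subject_id]
        out = []
        for row in sub.itertuples(index=False):
            succ = row.success
            out.append(TrialRecord(
                trial_index=int(row.trial_index),
                reward_apples=float(row.reward_apples),
                effort_prop=float(row.effort_prop),
                accepted=bool(row.accepted),
                exertion_omitted=bool(row.exertion_omitted),
                success=None if pd.isna(succ) else bool(succ),
            ))
        return out


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def draw_subjects(spec: GroupSpec, n: int, seed: int,
                  constraints: Optional[Mapping[str, float]] = None,
                  id_prefix: str = "") -> List[SubjectProfile]:
    """Draw ``n`` subjects from the group's population distributions.

    Free parameters come from (correlated) normals; ``constraints`` fills in
    clamped terms (default: LinE = -15, matching the constrained model).
    """
    if n < 1:
        raise SpecError("n must be >= 1")
    if constraints is None:
        constraints = {"LinE": -15.0}
    rng = np.random.default_rng(seed)
    ages = _truncated_normal(rng, spec.age_mean, spec.age_sd,
                             spec.age_bounds[0], spec.age_bounds[1], n)
    mvcs = np.maximum(rng.normal(spec.mvc_mean, spec.mvc_sd, n), 50.0)
    zK = rng.normal(size=n)
    zE = rng.normal(size=n)
    rho = spec.k_e2_corr
    draws = {}
    for term in spec.param_means:
        m, s = spec.param_means[term], spec.param_sds[term]
        if term == "K":
            draws[term] = m + s * zK
        elif term == "E2":
            draws[term] = m + s * (rho * zK + math.sqrt(1 - rho ** 2) * zE)
        else:
            draws[term] = rng.normal(m, s, n)
    if "K" in draws:
        draws["K"] = draws["K"] + spec.age_effect_on_k * (ages - spec.age_mean)
    factors = rng.normal(size=(n, len(FACTOR_NAMES))) + np.asarray(spec.symptom_shifts)

    subjects = []
    for i in range(n):
        d = {t: float(v[i]) for t, v in draws.items()}
        for t, c in constraints.items():
            d.setdefault(t, float(c))
        pv = ParamVector(K=d.get("K", 0.0), LinR=d.get("LinR", 0.0),
                         LinE=d.get("LinE", 0.0), E2=d.get("E2", 0.0))
        subjects.append(SubjectProfile(
            subject_id=f"{id_prefix}{spec.label}_{i:03d}",
            group=spec.label,
            age=float(ages[i]),
            params=pv,
            mvc=float(mvcs[i]),
            factors=factors[i],
            success_intercept=spec.success_intercept,
            success_slope=spec.success_slope,
        ))
    return subjects


def simulate_exertion(subject: SubjectProfile, effort_prop: float,
                      rng: np.random.Generator) -> bool:
    """Draw an exertion success from P(success | e) = logistic(a - b*e).

    The default (a=6, b=4.5) is monotonically decreasing in effort and
    keeps the success rate at the top 0.8-MVC level above 85%, consistent
    with individually calibrated effort levels.
    """
    if not (0 < effort_prop <= 1):
        raise SpecError("effort must lie in (0, 1]")
    p = expit(subject.success_intercept - subject.success_slope * effort_prop)
    return bool(rng.random() < p)


def simulate_choices(subject: SubjectProfile, schedule: TrialSchedule,
                     model: ModelSpec, seed: int,
                     omission_fraction: float = 0.25) -> List[TrialRecord]:
    """Simulate one session: accept/refuse draws, omission flags, exertion."""
    rng = np.random.default_rng(seed)
    trials = list(schedule.trials)
    rewards = np.array([t[1] for t in trials])
    efforts = np.array([t[2] for t in trials])
    X, offset = model.design_matrix(rewards, efforts)
    pd_ = subject.params.as_dict()
    theta = np.array([pd_[t] for t in model.free_in_order])
    p = expit(X @ theta + offset)
    accepted = rng.random(len(trials)) < p
    accepted_idx = [trials[i][0] for i in range(len(trials)) if accepted[i]]
    omitted = assign_exertion_omission(accepted_idx, omission_fraction)
    records = []
    for i, (idx, r, e) in enumerate(trials):
        acc = bool(accepted[i])
        om = acc and idx in omitted
        succ = None
        if acc and not om:
            succ = simulate_exertion(subject, e, rng)
        records.append(TrialRecord(trial_index=idx, reward_apples=r,
                                   effort_prop=e, accepted=acc,
                                   exertion_omitted=om, success=succ))
    return records


def simulate_questionnaires(subject: SubjectProfile,
                            loading_matrix: Optional[pd.DataFrame] = None,
                            noise_sd: float = 0.5,
                            seed: int = 0) -> Dict[str, float]:
    """Observed questionnaire totals: loadings x latent factors + noise."""
    if loading_matrix is None:
        loading_matrix = default_loading_matrix()
    L = np.asarray(loading_matrix, dtype=float)
    if L.shape[1] != len(FACTOR_NAMES):
        raise SpecError("loading matrix must have one column per factor")
    if len(subject.factors) != L.shape[1]:
        raise SpecError("factor-score dimension mismatch")
    rng = np.random.default_rng(seed)
    totals = L @ np.asarray(subject.factors) + rng.normal(0, noise_sd, L.shape[0])
    return {inst: float(v) for inst, v in zip(loading_matrix.index, totals)}


def generate_cohort(specs: Sequence[GroupSpec], sizes: Sequence[int],
                    design: DesignGrid = DesignGrid(), seed: int = 0,
                    model: Optional[ModelSpec] = None,
                    n_miscalibrated: int = 0,
                    loading_matrix: Optional[pd.DataFrame] = None,
                    questionnaire_noise_sd: float = 0.5) -> CohortData:
    """Generate a complete cohort: subjects, schedules, choices, questionnaires.

    ``n_miscalibrated`` subjects (spread round-robin over groups) are flagged
    as having failed the highest practice effort level; they still produce
    data, so the downstream exclusion filter can be exercised.
    """
    specs = list(specs)
    sizes = list(sizes)
    if len(specs) != len(sizes):
        raise SpecError("one size per group spec required")
    if model is None:
        model = constrained_winning_spec()
    root = np.random.SeedSequence(seed)
    part_rows: List[dict] = []
    trial_rows: List[dict] = []
    all_subjects: List[SubjectProfile] = []
    for spec, n, ss in zip(specs, sizes, root.spawn(max(len(specs), 1))):
        if n == 0:
            continue
        child = ss.generate_state(1)[0] % (2 ** 31)
        all_subjects.extend(draw_subjects(spec, n, int(child),
                                          constraints=dict(model.constraints)))
    # flag mis-calibrated subjects round-robin across the cohort
    for j in range(min(n_miscalibrated, len(all_subjects))):
        step = max(1, len(all_subjects) // max(n_miscalibrated, 1))
        all_subjects[(j * step) % len(all_subjects)].practice_pass_high = False
    flagged = sum(not s.practice_pass_high for s in all_subjects)
    if n_miscalibrated and flagged < min(n_miscalibrated, len(all_subjects)):
        for s in all_subjects:
            if flagged >= n_miscalibrated:
                break
            if s.practice_pass_high:
                s.practice_pass_high = False
                flagged += 1

    sub_seeds = root.spawn(len(all_subjects) + 1)[1:] if all_subjects else []
    for subject, ss in zip(all_subjects, sub_seeds):
        s1, s2, s3 = (int(x % (2 ** 31)) for x in ss.generate_state(3))
        schedule = build_schedule(design, s1)
        records = simulate_choices(subject, schedule, model, s2)
        subject.questionnaires = simulate_questionnaires(
            subject, loading_matrix, questionnaire_noise_sd, s3)
        row = {
            "participant_id": subject.subject_id,
            "group": subject.group,
            "age": subject.age,
            "mvc": subject.mvc,
            "practice_pass_high": subject.practice_pass_high,
        }
        row.update({f"true_{k}": v for k, v in subject.params.as_dict().items()})
        row.update(subject.questionnaires)
        part_rows.append(row)
        for rec in records:
            trial_rows.append({
                "participant_id": subject.subject_id,
                "group": subject.group,
                "age": subject.age,
                "trial_index": rec.trial_index,
                "reward_apples": rec.reward_apples,
                "effort_prop": rec.effort_prop,
                "accepted": int(rec.accepted),
                "exertion_omitted": int(rec.exertion_omitted),
                "success": (np.nan if rec.success is None else float(rec.success)),
            })
    part_cols = ["participant_id", "group", "age", "mvc", "practice_pass_high"]
    trial_cols = ["participant_id", "group", "age", "trial_index", "reward_apples",
                  "effort_prop", "accepted", "exertion_omitted", "success"]
    participants = (pd.DataFrame(part_rows) if part_rows
                    else pd.DataFrame(columns=part_cols))
    trials = (pd.DataFrame(trial_rows) if trial_rows
              else pd.DataFrame(columns=trial_cols))
    return CohortData(participants=participants, trials=trials)
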