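"""Model-agnostic group statistics for AGT cohorts.

Covers the acceptance-rate analyses (arcsine transform, repeated-measures
ANOVA over the reward x effort grid with Greenhouse-Geisser correction,
planned group contrasts), ANCOVA on fitted model parameters, the
questionnaire factor analysis (ML extraction, Promax rotation), parameter-
symptom correlations, the analytic one-way ANOVA power computation, and
the calibration-failure exclusion filter.

The mixed repeated-measures ANOVA is computed with the orthonormal
within-contrast general linear model: each within-subject effect is
projected onto an orthonormal contrast basis, the between-subject design
(sum-coded group, mean-centred covariate) is fitted to the transformed
responses, and the averaged univariate F is formed from type-III
hypothesis and error SSCP traces.  Greenhouse-Geisser epsilon and
Mauchly's sphericity test come from the error covariance in contrast
space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import null_space

logger = logging.getLogger(__name__)

__all__ = [
    "StatsError",
    "AcceptanceTable",
    "ContrastResult",
    "FactorSolution",
    "aggregate_acceptance",
    "arcsine_transform",
    "rm_anova",
    "planned_contrasts",
    "ancova_parameters",
    "AncovaReport",
    "efa",
    "correlate_params_factors",
    "anova_power",
    "exclusion_filter",
    "PLANNED_CONTRASTS",
]


class StatsError(ValueError):
    """Invalid statistical design or data."""


# ---------------------------------------------------------------------------
# acceptance aggregation


@dataclass
class AcceptanceTable:
    """Per-subject acceptance proportions over the reward x effort grid.

    ``cells`` is indexed by participant with one column per (reward,
    effort) cell; ``overall`` is the mean over all trials; ``meta`` carries
    group and age.
    """

    cells: pd.DataFrame
    overall: pd.Series
    meta: pd.DataFrame
    repetitions: int

    @property
    def reward_levels(self) -> np.ndarray:
        return np.unique([c[0] for c in self.cells.columns])

    @property
    def effort_levels(self) -> np.ndarray:
        return np.unique([c[1] for c in self.cells.columns])


def aggregate_acceptance(trials: pd.DataFrame) -> AcceptanceTable:
    """Fold trial records into per-cell acceptance proportions.

    Every subject must have the same complete cell grid with equal
    repetitions; the overall rate is the plain mean over trials (cells are
    equally weighted by design).
    """
    required = {"participant_id", "reward_apples", "effort_prop", "accepted"}
    missing = required - set(trials.columns)
    if missing:
        raise StatsError(f"trial table lacks columns {sorted(missing)}")
    counts = trials.groupby(
        ["participant_id", "reward_apples", "effort_prop"])["accepted"]
    tab = counts.agg(["mean", "count"]).unstack(["reward_apples", "effort_prop"])
    rates = tab["mean"]
    ns = tab["count"]
    if rates.isna().any().any():
        bad = rates.index[rates.isna().any(axis=1)].tolist()
        raise StatsError(f"missing design cells for subjects {bad[:5]}")
    reps = ns.to_numpy()
    if not np.all(reps == reps.flat[0]):
        raise StatsError("unequal repetitions across cells")
    rates = rates.sort_index(axis=1)
    overall = trials.groupby("participant_id")["accepted"].mean().reindex(rates.index)
    meta_cols = [c for c in ("group", "age") if c in trials.columns]
    meta = (trials.drop_duplicates("participant_id")
            .set_index("participant_id")[meta_cols].reindex(rates.index))
    return AcceptanceTable(cells=rates, overall=overall, meta=meta,
                           repetitions=int(reps.flat[0]))


def arcsine_transform(p):
    """Variance-stabilising arcsin(sqrt(p)) transform for proportions."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise StatsError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# repeated-measures ANOVA (orthonormal contrast GLM)


def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """Orthonormal basis of the contrast space (orthogonal to the mean)."""
    return null_space(np.ones((1, levels)))


def _sum_code(groups: pd.Series) -> Tuple[np.ndarray, List[str]]:
    labels = sorted(groups.unique())
    n, k = len(groups), len(labels)
    X = np.zeros((n, k - 1))
    for j, lab in enumerate(labels[:-1]):
        X[:, j] = (groups == lab).astype(float) - (groups == labels[-1]).astype(float)
    return X, labels


def _term_f(Y, X, cols, df_h):
    """Type-III averaged univariate F for the coefficients in ``cols``."""
    n, q = Y.shape
    G = np.linalg.pinv(X.T @ X)
    B = G @ X.T @ Y
    resid = Y - X @ B
    E = resid.T @ resid
    df_e = n - np.linalg.matrix_rank(X)
    L = np.zeros((len(cols), X.shape[1]))
    for i, c in enumerate(cols):
        L[i, c] = 1.0
    M = L @ G @ L.T
    LB = L @ B
    H = LB.T @ np.linalg.solve(M, LB)
    F = (np.trace(H) / (q * df_h)) / (np.trace(E) / (q * df_e))
    return F, q * df_h, q * df_e, E, df_e


def _gg_epsilon(E: np.ndarray, df_e: int) -> Tuple[float, float, float]:
    """Greenhouse-Geisser epsilon and Mauchly's test from the error SSCP."""
    q = E.shape[0]
    if q == 1:
        return 1.0, 1.0, 1.0
    S = E / df_e
    tr = np.trace(S)
    eps = tr ** 2 / (q * np.trace(S @ S))
    eps = float(np.clip(eps, 1.0 / q, 1.0))
    det = np.linalg.det(S)
    if det <= 0:
        return eps, 0.0, 0.0
    W = det / ((tr / q) ** q)
    chi2 = -(df_e - (2 * q ** 2 + q + 2) / (6.0 * q)) * np.log(W)
    dof = q * (q + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, dof))
    return eps, float(W), p


def rm_anova(table: AcceptanceTable, between: Optional[str] = "group",
             covariate: Optional[str] = "age", transform: bool = True,
             sphericity_alpha: float = 0.05) -> pd.DataFrame:
    """Mixed repeated-measures ANOVA over the reward x effort grid.

    Within-subject effects (reward, effort, their interaction) get
    Greenhouse-Geisser-corrected degrees of freedom whenever Mauchly's test
    rejects sphericity at ``sphericity_alpha``.  ``between`` adds a
    between-subject group factor and its interactions; ``covariate`` (mean-
    centred internally) is partialled from every stratum.  Acceptance
    proportions are arcsine transformed by default.
    """
    Y = table.cells.to_numpy(dtype=float)
    if transform:
        Y = arcsine_transform(Y)
    n = Y.shape[0]
    r_levels = table.reward_levels
    e_levels = table.effort_levels
    La, Lb = len(r_levels), len(e_levels)
    if Y.shape[1] != La * Lb:
        raise StatsError("cell grid is not a complete crossing")

    parts = [np.ones((n, 1))]
    names: List[Tuple[str, List[int]]] = []
    col = 1
    if between is not None:
        if between not in table.meta.columns:
            raise StatsError(f"no between-subject column {between!r}")
        g = table.meta[between]
        sizes = g.value_counts()
        if (sizes < 2).any():
            raise StatsError(
                f"factor {between!r} deficient: groups {sizes[sizes < 2].index.tolist()} "
                "have fewer than 2 subjects")
        Xg, _ = _sum_code(g)
        parts.append(Xg)
        names.append((between, list(range(col, col + Xg.shape[1]))))
        col += Xg.shape[1]
    if covariate is not None:
        if covariate not in table.meta.columns:
            raise StatsError(f"no covariate column {covariate!r}")
        z = table.meta[covariate].to_numpy(dtype=float)
        z = z - z.mean()          # covariates are mean-corrected
        parts.append(z[:, None])
        names.append((covariate, [col]))
        col += 1
    X = np.column_stack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        deficient = between if between is not None else covariate
        raise StatsError(f"singular design (factor {deficient!r})")

    C_r = _orthonormal_contrasts(La)
    C_e = _orthonormal_contrasts(Lb)
    j_r = np.full((La, 1), 1.0 / np.sqrt(La))
    j_e = np.full((Lb, 1), 1.0 / np.sqrt(Lb))
    within = {
        "reward": np.kron(C_r, j_e),
        "effort": np.kron(j_r, C_e),
        "reward:effort": np.kron(C_r, C_e),
    }

    rows = []
    for wname, M in within.items():
        Yw = Y @ M
        terms = [(wname, [0], 1)]
        for tname, cols in names:
            terms.append((f"{wname}:{tname}", cols, len(cols)))
        for label, cols, df_h in terms:
            F, df1, df2, E, df_e = _term_f(Yw, X, cols, df_h)
            eps, W, p_sph = _gg_epsilon(E, df_e)
            violated = p_sph < sphericity_alpha
            p_unc = float(sps.f.sf(F, df1, df2))
            p_gg = float(sps.f.sf(F, eps * df1, eps * df2))
            rows.append({
                "effect": label, "F": float(F), "df1": df1, "df2": df2,
                "p": p_unc, "mauchly_W": W, "mauchly_p": p_sph,
                "epsilon": eps, "sphericity_violated": bool(violated),
                "df1_gg": eps * df1, "df2_gg": eps * df2, "p_gg": p_gg,
                "p_reported": p_gg if violated else p_unc,
            })
    # between-subject stratum on the subject means
    j_full = np.kron(j_r, j_e)
    Yb = Y @ j_full
    for tname, cols in names:
        F, df1, df2, _, _ = _term_f(Yb, X, cols, len(cols))
        p_unc = float(sps.f.sf(F, df1, df2))
        rows.append({
            "effect": tname, "F": float(F), "df1": df1, "df2": df2,
            "p": p_unc, "mauchly_W": np.nan, "mauchly_p": np.nan,
            "epsilon": np.nan, "sphericity_violated": False,
            "df1_gg": df1, "df2_gg": df2, "p_gg": p_unc, "p_reported": p_unc,
        })
    return pd.DataFrame(rows).set_index("effect")


# ---------------------------------------------------------------------------
# planned contrasts and ANCOVA


@dataclass
class ContrastResult:
    """A two-pool group contrast: effect size on raw values, test on
    (optionally transformed) covariate-adjusted values."""

    label: str
    cohens_d: float
    statistic: float
    p_value: float
    n_first: int
    n_second: int


#: The two planned pools: depression history vs none, any vulnerability vs none.
PLANNED_CONTRASTS: Tuple[Tuple[str, Tuple[str, ...], Tuple[str, ...]], ...] = (
    ("MDD+REM vs REL+CTR", ("MDD", "REM"), ("REL", "CTR")),
    ("MDD+REM+REL vs CTR", ("MDD", "REM", "REL"), ("CTR",)),
)


def _pooled_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                 / (na + nb - 2))
    return float((a.mean() - b.mean()) / sp)


def planned_contrasts(values: pd.Series, groups: pd.Series,
                      covariate: Optional[pd.Series] = None,
                      test_values: Optional[pd.Series] = None,
                      contrasts=PLANNED_CONTRASTS) -> List[ContrastResult]:
    """Pooled-group contrasts.

    Cohen's d uses the raw ``values`` and the pooled standard deviation
    (covariate-free); the significance test is run on ``test_values``
    (default: the raw values) in a linear model with the mean-centred
    covariate partialled.
    """
    import statsmodels.api as sm

    values = pd.Series(values)
    groups = pd.Series(groups).reindex(values.index)
    tv = values if test_values is None else pd.Series(test_values).reindex(values.index)
    out = []
    for label, first, second in contrasts:
        in_first = groups.isin(first)
        in_second = groups.isin(second)
        if in_first.sum() == 0 or in_second.sum() == 0:
            raise StatsError(f"contrast {label!r} has an empty pool")
        mask = in_first | in_second
        x = in_first[mask].astype(float)
        design = pd.DataFrame({"const": 1.0, "pool": x})
        if covariate is not None:
            z = pd.Series(covariate).reindex(values.index)[mask].astype(float)
            design["cov"] = z - z.mean()
        fit = sm.OLS(tv[mask].astype(float), design).fit()
        d = _pooled_d(values[in_first].to_numpy(dtype=float),
                      values[in_second].to_numpy(dtype=float))
        out.append(ContrastResult(
            label=label, cohens_d=d,
            statistic=float(fit.tvalues["pool"]),
            p_value=float(fit.pvalues["pool"]),
            n_first=int(in_first.sum()), n_second=int(in_second.sum()),
        ))
    return out


@dataclass
class AncovaReport:
    """Per-parameter group ANCOVA with pairwise post-hocs."""

    omnibus: pd.DataFrame       # parameter, F, df1, df2, p
    posthoc: pd.DataFrame       # parameter, A, B, t, p, p_holm, d
    skipped: List[str] = field(default_factory=list)


def ancova_parameters(estimates: pd.DataFrame, group_col: str = "group",
                      age: Optional[pd.Series] = None,
                      parameters: Optional[Sequence[str]] = None) -> AncovaReport:
    """One-way group ANCOVA per fitted parameter, age as covariate.

    Constant (constrained) parameters are excluded with a logged notice.
    Pairwise post-hoc comparisons report unadjusted p-values alongside a
    Holm-adjusted column; Cohen's d excludes the covariate.
    """
    import pingouin as pg
    from statsmodels.stats.multitest import multipletests

    if group_col not in estimates.columns:
        raise StatsError(f"no group column {group_col!r}")
    groups = estimates[group_col]
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise StatsError("ANCOVA needs at least 2 groups")
    if parameters is None:
        parameters = [c for c in estimates.columns
                      if c != group_col and np.issubdtype(estimates[c].dtype, np.number)]
    skipped, om_rows, ph_rows = [], [], []
    for p in parameters:
        vals = estimates[p].astype(float)
        if np.std(vals) < 1e-12:
            logger.info("parameter %s is constant (constrained); excluded from ANCOVA", p)
            skipped.append(p)
            continue
        df = pd.DataFrame({"y": vals, "group": groups})
        if age is not None:
            z = pd.Series(age).reindex(estimates.index).astype(float)
            df["age_c"] = z - z.mean()
            res = pg.ancova(data=df, dv="y", between="group", covar="age_c")
        else:
            res = pg.anova(data=df, dv="y", between="group", detailed=True)
        row = res[res["Source"] == "group"].iloc[0]
        df_resid = (res[res["Source"] == "Residual"]["DF"].iloc[0]
                    if "Residual" in set(res["Source"]) else len(df) - len(labels) - 1)
        om_rows.append({"parameter": p, "F": float(row["F"]),
                        "df1": int(row["DF"]), "df2": int(df_resid),
                        "p": float(row["p_unc"])})
        import statsmodels.api as sm
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = labels[i], labels[j]
                mask = groups.isin([a, b])
                x = (groups[mask] == a).astype(float)
                design = pd.DataFrame({"const": 1.0, "grp": x})
                if age is not None:
                    zz = df.loc[mask, "age_c"]
                    design["cov"] = zz - zz.mean()
                fit = sm.OLS(vals[mask], design).fit()
                ph_rows.append({
                    "parameter": p, "A": a, "B": b,
                    "t": float(fit.tvalues["grp"]),
                    "p": float(fit.pvalues["grp"]),
                    "d": _pooled_d(vals[groups == a].to_numpy(),
                                   vals[groups == b].to_numpy()),
                })
    posthoc = pd.DataFrame(ph_rows)
    if len(posthoc):
        holm = np.empty(len(posthoc))
        for p in posthoc["parameter"].unique():
            m = posthoc["parameter"] == p
            holm[m.to_numpy()] = multipletests(posthoc.loc[m, "p"], method="holm")[1]
        posthoc["p_holm"] = holm
    return AncovaReport(omnibus=pd.DataFrame(om_rows), posthoc=posthoc,
                        skipped=skipped)


# ---------------------------------------------------------------------------
# questionnaire factor analysis


def _varimax(L: np.ndarray, tol: float = 1e-10, max_iter: int = 1000):
    p, k = L.shape
    R = np.eye(k)
    total = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        grad = L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        new = s.sum()
        if new < total * (1 + tol):
            break
        total = new
    return L @ R, R


def _promax(L: np.ndarray, kappa: int = 4):
    """Promax oblique rotation from the varimax solution (R convention)."""
    V, R_vm = _varimax(L)
    # column-sign convention: largest loading positive
    signs = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    V = V * signs
    target = np.sign(V) * np.abs(V) ** kappa
    U, *_ = np.linalg.lstsq(V, target, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    pattern = V @ U
    # accumulated rotation of the unrotated loadings
    T = (R_vm * signs) @ U
    phi = np.linalg.inv(T.T @ T)
    return pattern, phi, T


@dataclass
class FactorSolution:
    """Obliquely rotated factor solution for questionnaire totals."""

    loadings: pd.DataFrame       # pattern matrix, instruments x factors
    phi: pd.DataFrame            # factor correlations
    scores: pd.DataFrame         # regression factor scores per subject
    uniquenesses: pd.Series
    rotation: str

    def salient(self, threshold: float = 0.3) -> pd.DataFrame:
        """Marker for loadings above the conventional salience threshold."""
        return self.loadings.abs() > threshold


def efa(totals: pd.DataFrame, n_factors: int = 4, rotation: str = "promax",
        kappa: int = 4) -> FactorSolution:
    """Exploratory factor analysis of questionnaire totals.

    Maximum-likelihood extraction on the standardised totals followed by an
    oblique Promax rotation (varimax orthogonal rotation is available with
    ``rotation='varimax'``).  Factor scores use Thurstone's regression
    method.  A warning is issued when there are fewer than five subjects
    per instrument.
    """
    from sklearn.decomposition import FactorAnalysis

    X = totals.to_numpy(dtype=float)
    n, p = X.shape
    if n < 5 * p:
        warnings.warn(f"only {n} subjects for {p} instruments "
                      "(fewer than the recommended 5 per instrument)")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd < 1e-12):
        raise StatsError("constant questionnaire column; correlation matrix singular")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    if np.linalg.matrix_rank(R) < p:
        raise StatsError("singular correlation matrix")
    fa = FactorAnalysis(n_components=n_factors, svd_method="lapack",
                        max_iter=5000, tol=1e-4)
    fa.fit(Z)
    L = fa.components_.T                      # p x k, correlation metric
    if rotation == "promax":
        pattern, phi, _ = _promax(L, kappa=kappa)
    elif rotation == "varimax":
        pattern, R_vm = _varimax(L)
        signs = np.sign(pattern[np.argmax(np.abs(pattern), axis=0),
                                np.arange(pattern.shape[1])])
        signs[signs == 0] = 1.0
        pattern = pattern * signs
        phi = np.eye(n_factors)
    else:
        raise StatsError(f"unknown rotation {rotation!r}")
    factor_names = [f"F{j + 1}" for j in range(n_factors)]
    loadings = pd.DataFrame(pattern, index=totals.columns, columns=factor_names)
    phi_df = pd.DataFrame(phi, index=factor_names, columns=factor_names)
    structure = pattern @ phi
    W = np.linalg.solve(R, structure)         # Thurstone regression weights
    scores = pd.DataFrame(Z @ W, index=totals.index, columns=factor_names)
    uniq = pd.Series(fa.noise_variance_, index=totals.columns)
    return FactorSolution(loadings=loadings, phi=phi_df, scores=scores,
                          uniquenesses=uniq, rotation=rotation)


def correlate_params_factors(estimates: pd.DataFrame, scores: pd.DataFrame,
                             parameters: Optional[Sequence[str]] = None,
                             subset: Optional[Sequence] = None) -> pd.DataFrame:
    """Pearson correlations between model parameters and symptom factors.

    ``subset`` restricts to a set of participants (e.g. one diagnostic
    pool); raw and Holm-adjusted p-values are reported side by side.
    """
    from statsmodels.stats.multitest import multipletests

    idx = estimates.index.intersection(scores.index)
    if subset is not None:
        idx = idx.intersection(pd.Index(subset))
    if len(idx) < 3:
        raise StatsError("need at least 3 aligned subjects")
    if parameters is None:
        parameters = [c for c in estimates.columns
                      if np.issubdtype(estimates[c].dtype, np.number)
                      and estimates.loc[idx, c].std() > 1e-12]
    rows = []
    for p in parameters:
        for f in scores.columns:
            r, pv = sps.pearsonr(estimates.loc[idx, p], scores.loc[idx, f])
            rows.append({"parameter": p, "factor": f, "r": float(r),
                         "p": float(pv), "n": len(idx)})
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p"], method="holm")[1]
    return out


# ---------------------------------------------------------------------------
# power and exclusions


def anova_power(n_total: int, k_groups: int, f: float,
                alpha: float = 0.05) -> float:
    """Power of the one-way fixed-effects ANOVA via the noncentral F.

    The noncentrality parameter is ``f**2 * n_total`` with numerator df
    ``k-1`` and denominator df ``n-k``.
    """
    if n_total <= k_groups or k_groups < 2:
        raise StatsError("need n_total > k_groups >= 2")
    if f <= 0 or not (0 < alpha < 1):
        raise StatsError("require f > 0 and alpha in (0, 1)")
    df1, df2 = k_groups - 1, n_total - k_groups
    crit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, f ** 2 * n_total))


def exclusion_filter(participants: pd.DataFrame,
                     flag_col: str = "practice_pass_high"
                     ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Remove participants who failed the highest practice effort level.

    Returns ``(retained, exclusion_log)``; idempotent.  Subjects unable to
    reach the top effort level during practice cannot produce interpretable
    choices at that level (mis-calibrated grip device).
    """
    if flag_col not in participants.columns:
        raise StatsError(f"no practice-outcome column {flag_col!r}")
    failed = ~participants[flag_col].astype(bool)
    log = pd.DataFrame({
        "participant_id": participants.loc[failed, "participant_id"]
        if "participant_id" in participants.columns
        else participants.index[failed],
        "reason": "failed highest practice effort level (mis-calibration)",
    })
    for pid in log["participant_id"]:
        logger.info("excluding %s: failed highest practice effort level", pid)
    return participants.loc[~failed].copy(), log.reset_index(drop=True)
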