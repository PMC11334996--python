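"""Same/different viewpoint-discrimination analysis.

The experimental chain this module covers, end to end:

* per-trial and per-participant exclusions (reaction-time window, 75%
  performance floor on the priming and main tasks);
* psychometric tables — P("same") / P("different") per object × axis type ×
  absolute rotation level;
* the **cardinal axis effect**: per object, the difference between cardinal
  and non-cardinal axes in the slope of P("different") between the 0° and 5°
  rotation levels (per-degree units). Positive = discrimination is better
  around the cardinal axis;
* a feasible-GLS factorial model of performance against rotation level ×
  axis type × image set, with the residual-variance structure selected by
  AIC among candidate groupings (heteroscedasticity across design cells is
  the norm for proportions);
* the small inferential toolbox the flow-model comparisons need: simple
  linear regression, paired t with Cohen's D, and the Wilcoxon signed-rank
  test with exact enumeration at small n.

Trial tables are plain pandas DataFrames with the documented column schema
(:data:`TRIAL_COLUMNS`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegeneratePredictorError,
    MissingCellError,
    ValidationError,
)

__all__ = [
    "TRIAL_COLUMNS",
    "ROTATION_LEVELS",
    "ExclusionCriteria",
    "ExclusionReport",
    "CardinalAxisEffect",
    "StatResult",
    "RegressionResult",
    "FGLSResult",
    "read_trials",
    "apply_exclusions",
    "psychometric_table",
    "cardinal_axis_effect",
    "cardinal_axis_effects",
    "fgls_factorial",
    "simple_regression",
    "paired_t_cohens_d",
    "wilcoxon_signed_rank",
]

#: Column schema of a trial table (one row per same/different trial).
TRIAL_COLUMNS = (
    "participant",
    "object",
    "image_set",
    "axis_type",
    "base_view",
    "rotation_level",
    "response",
    "rt_ms",
)

#: The seven signed rotation offsets shown to observers, in degrees.
ROTATION_LEVELS = (0, 5, -5, 10, -10, 15, -15)


@dataclass(frozen=True)
class ExclusionCriteria:
    """Trial/participant exclusion thresholds.

    ``front_tolerance_deg`` is consumed by the front-judgement analysis; it
    lives here so one object carries all exclusion policy.
    """

    rt_min_ms: float = 300.0
    rt_max_ms: float = 5000.0
    performance_min: float = 0.75
    front_tolerance_deg: float = 45.0

    def __post_init__(self) -> None:
        if not self.rt_min_ms < self.rt_max_ms:
            raise ValidationError("need rt_min < rt_max")
        if not 0.0 < self.performance_min < 1.0:
            raise ValidationError("performance_min must be in (0, 1)")


@dataclass(frozen=True)
class ExclusionReport:
    n_input: int
    n_retained: int
    n_rt_excluded: int
    excluded_participants: dict[str, str]  # participant -> rule that removed them

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_rt_excluded": self.n_rt_excluded,
            "excluded_participants": dict(self.excluded_participants),
        }


@dataclass(frozen=True)
class CardinalAxisEffect:
    """Slope of P("different") between 0° and 5°, cardinal minus non-cardinal."""

    object: str
    slope_cardinal: float  # change in P(different) per degree
    slope_noncardinal: float

    @property
    def effect(self) -> float:
        return self.slope_cardinal - self.slope_noncardinal


@dataclass(frozen=True)
class StatResult:
    """One inferential statistic: kind ∈ {t, F, z, W}, df, p, effect size."""

    kind: str
    value: float
    df: tuple[float, ...]
    p: float
    effect_size: float | None = None
    effect_kind: str | None = None  # "cohen_d" | "r" | "r_squared"
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "value": self.value,
            "df": list(self.df),
            "p": self.p,
            "effect_size": self.effect_size,
            "effect_kind": self.effect_kind,
            "note": self.note,
        }


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    stat: StatResult  # F with (1, n-2) df


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial table CSV and validate the schema and value domains."""
    trials = pd.read_csv(path)
    return validate_trials(trials)


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValidationError(f"trial table missing columns: {sorted(missing)}")
    bad_levels = set(trials["rotation_level"].unique()) - set(ROTATION_LEVELS)
    if bad_levels:
        raise ValidationError(f"unknown rotation levels: {sorted(bad_levels)}")
    if (trials["rt_ms"] <= 0).any():
        raise ValidationError("reaction times must be positive")
    bad_resp = set(trials["response"].unique()) - {"same", "different"}
    if bad_resp:
        raise ValidationError(f"responses must be same/different, got {bad_resp}")
    return trials


def main_task_performance(trials: pd.DataFrame) -> pd.Series:
    """Per-participant proportion correct on the unambiguous trials.

    0° trials are correct when answered "same"; |rotation| ≥ 10° trials when
    answered "different". 5° trials are genuinely ambiguous at threshold and
    are not counted toward the criterion.
    """
    lvl = trials["rotation_level"].abs()
    scored = trials[(lvl == 0) | (lvl >= 10)]
    correct = np.where(
        scored["rotation_level"].abs() == 0,
        scored["response"] == "same",
        scored["response"] == "different",
    )
    return pd.Series(correct, index=scored["participant"]).groupby(level=0).mean()


def apply_exclusions(
    trials: pd.DataFrame,
    criteria: ExclusionCriteria = ExclusionCriteria(),
    priming_scores: Mapping[str, float] | pd.Series | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the reaction-time and performance exclusion rules.

    Both rules are evaluated on the *input* set and then applied jointly, so
    the outcome does not depend on rule order. Participants failing the
    performance floor on the priming task or the main task lose all their
    trials; individual trials outside the RT window are dropped.
    """
    trials = validate_trials(trials)
    participants = trials["participant"].unique()
    if priming_scores is not None:
        priming = pd.Series(priming_scores, dtype=float)
        unknown = set(participants) - set(priming.index)
        if unknown:
            raise ValidationError(
                f"participants missing from priming table: {sorted(map(str, unknown))}"
            )
    else:
        priming = None

    rt_ok = trials["rt_ms"].between(criteria.rt_min_ms, criteria.rt_max_ms)
    perf = main_task_performance(trials)

    removed: dict[str, str] = {}
    for p in participants:
        if priming is not None and priming[p] < criteria.performance_min:
            removed[str(p)] = "priming_performance"
        elif perf.get(p, 1.0) < criteria.performance_min:
            removed[str(p)] = "main_task_performance"
    keep_participant = ~trials["participant"].astype(str).isin(removed)
    kept = trials[rt_ok & keep_participant]
    report = ExclusionReport(
        n_input=len(trials),
        n_retained=len(kept),
        n_rt_excluded=int((~rt_ok).sum()),
        excluded_participants=removed,
    )
    return kept, report


def psychometric_table(trials: pd.DataFrame, pool_sign: bool = True) -> pd.DataFrame:
    """Response proportions per (object, axis_type, rotation level).

    With ``pool_sign`` (default) the ±k levels are pooled into |k|, matching
    how performance is reported per unsigned level. Cells that received no
    trials are simply absent from the table (never reported as zero).
    Columns: object, axis_type, rotation_level, n_trials, p_same, p_different.
    """
    if trials.empty:
        raise ValidationError("empty trial set")
    work = trials.copy()
    if pool_sign:
        work["rotation_level"] = work["rotation_level"].abs()
    grouped = work.groupby(["object", "axis_type", "rotation_level"], sort=True)
    table = grouped["response"].agg(
        n_trials="size", p_same=lambda r: np.mean(r == "same")
    )
    table["p_different"] = 1.0 - table["p_same"]
    return table.reset_index()


def _cell(table: pd.DataFrame, obj: str, axis: str, level: float, col: str) -> float:
    row = table[
        (table["object"] == obj)
        & (table["axis_type"] == axis)
        & (table["rotation_level"] == level)
    ]
    if row.empty:
        raise MissingCellError(f"no cell ({obj!r}, {axis!r}, {level}°)")
    return float(row[col].iloc[0])


def cardinal_axis_effect(table: pd.DataFrame, obj: str) -> CardinalAxisEffect:
    """Per-object cardinal axis effect from a (sign-pooled) psychometric table.

    slope = (P_different(5°) − P_different(0°)) / 5 for each axis type;
    effect = cardinal slope − non-cardinal slope.
    """
    slopes = {}
    for axis in ("cardinal", "non-cardinal"):
        p0 = _cell(table, obj, axis, 0, "p_different")
        p5 = _cell(table, obj, axis, 5, "p_different")
        slopes[axis] = (p5 - p0) / 5.0
    return CardinalAxisEffect(str(obj), slopes["cardinal"], slopes["non-cardinal"])


def cardinal_axis_effects(table: pd.DataFrame) -> pd.DataFrame:
    """Cardinal axis effect for every object in the table (tidy frame)."""
    rows = []
    for obj in table["object"].unique():
        eff = cardinal_axis_effect(table, obj)
        rows.append(
            {
                "object": eff.object,
                "slope_cardinal": eff.slope_cardinal,
                "slope_noncardinal": eff.slope_noncardinal,
                "effect": eff.effect,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feasible GLS factorial model
# ---------------------------------------------------------------------------

#: Candidate residual-variance groupings, compared by AIC.
VARIANCE_STRUCTURES = ("homoscedastic", "axis_type", "rotation_level", "cell")

_TERMS = (
    "intercept",
    "rotation_level",
    "axis_type",
    "image_set",
    "rotation_level:axis_type",
    "rotation_level:image_set",
    "axis_type:image_set",
    "rotation_level:axis_type:image_set",
)


@dataclass(frozen=True)
class FGLSResult:
    params: pd.Series
    stats: list[StatResult] = field(repr=False)
    variance_structure: str = "homoscedastic"
    aic_by_structure: dict[str, float] = field(default_factory=dict)
    group_variances: pd.Series | None = field(default=None, repr=False)
    n_iterations: int = 0

    def stat_for(self, term: str) -> StatResult:
        for s in self.stats:
            if s.note == term:
                return s
        raise KeyError(term)


def _design_matrix(data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Full-factorial design with sum-to-zero coding.

    rotation_level enters as a centered numeric covariate; the two-level
    factors as ±1, so each coefficient's Wald test is the marginal
    (Type-III-style) test of its term.
    """
    r = data["rotation_level"].astype(float).to_numpy()
    r = r - r.mean()
    axis_levels = sorted(data["axis_type"].unique())
    set_levels = sorted(data["image_set"].unique())
    if len(axis_levels) != 2 or len(set_levels) != 2:
        raise ValidationError(
            "factorial model expects exactly two axis_type and two image_set levels"
        )
    a = np.where(data["axis_type"] == axis_levels[0], 1.0, -1.0)
    s = np.where(data["image_set"] == set_levels[0], 1.0, -1.0)
    cols = [np.ones(len(data)), r, a, s, r * a, r * s, a * s, r * a * s]
    x = np.column_stack(cols)
    return x, list(_TERMS)


def _group_codes(data: pd.DataFrame, structure: str) -> np.ndarray:
    if structure == "homoscedastic":
        return np.zeros(len(data), dtype=np.int64)
    if structure == "axis_type":
        key = data["axis_type"].astype(str)
    elif structure == "rotation_level":
        key = data["rotation_level"].astype(str)
    elif structure == "cell":
        key = (
            data["rotation_level"].astype(str)
            + "|"
            + data["axis_type"].astype(str)
            + "|"
            + data["image_set"].astype(str)
        )
    else:
        raise ValidationError(f"unknown variance structure {structure!r}")
    return pd.factorize(key)[0]


def _fgls_fit(
    y: np.ndarray, x: np.ndarray, groups: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int]:
    """Iterated feasible GLS with per-group residual variances.

    Returns (beta, cov_beta, df-corrected group variances per observation,
    ML log-likelihood, iterations). Wald variances carry the N/(N−p) df
    correction so the homoscedastic case reproduces OLS exactly; the
    likelihood (for AIC) uses the ML variances.
    """
    n, p = x.shape
    n_groups = groups.max() + 1
    w = np.ones(n)
    beta_old = None
    var_ml_obs = np.ones(n)
    for it in range(1, max_iter + 1):
        xw = x * w[:, None]
        xtx = xw.T @ x
        beta = np.linalg.solve(xtx, xw.T @ y)
        resid = y - x @ beta
        var_ml = np.array(
            [np.mean(resid[groups == g] ** 2) for g in range(n_groups)]
        )
        if np.any(var_ml <= 0):
            raise ValidationError("a variance group fits its data exactly")
        var_ml_obs = var_ml[groups]
        w = 1.0 / (var_ml_obs * n / (n - p))
        if beta_old is not None and np.max(np.abs(beta - beta_old)) <= tol * (
            1 + np.max(np.abs(beta))
        ):
            beta_old = beta
            break
        beta_old = beta
    xw = x * w[:, None]
    cov = np.linalg.inv(xw.T @ x)
    resid = y - x @ beta_old
    loglik = -0.5 * float(
        np.sum(np.log(2 * np.pi * var_ml_obs) + resid**2 / var_ml_obs)
    )
    return beta_old, cov, var_ml_obs * n / (n - p), loglik, it


def fgls_factorial(
    data: pd.DataFrame,
    response: str = "p_different",
    variance_structures: Sequence[str] = VARIANCE_STRUCTURES,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> FGLSResult:
    """Feasible GLS for ``response ~ rotation_level × axis_type × image_set``.

    ``data`` is one row per analysis unit (typically a participant × cell
    proportion) with the three factor columns plus the response. For each
    candidate variance structure the model is fit by iterating (OLS →
    per-group residual variances → weighted refit) to convergence; the
    structure with the lowest AIC wins and its marginal Wald F-tests
    (df1 = 1 each under this coding) are reported.
    """
    for col in ("rotation_level", "axis_type", "image_set", response):
        if col not in data.columns:
            raise ValidationError(f"data lacks column {col!r}")
    y = data[response].to_numpy(float)
    x, terms = _design_matrix(data)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the aliased columns via the QR diagonal
        diag = np.abs(np.diag(np.linalg.qr(x, mode="r")))
        aliased = [terms[i] for i in np.argsort(diag)[: x.shape[1] - rank]]
        raise ValidationError(f"design is rank-deficient; aliased terms: {aliased}")

    fits = {}
    for structure in variance_structures:
        groups = _group_codes(data, structure)
        # guard: every variance group needs enough residual df to estimate
        counts = np.bincount(groups)
        if counts.min() < 3:
            continue
        beta, cov, var_obs, loglik, iters = _fgls_fit(y, x, groups, tol, max_iter)
        k = x.shape[1] + groups.max() + 1
        fits[structure] = (beta, cov, var_obs, -2 * loglik + 2 * k, iters, groups)
    if not fits:
        raise ValidationError("no admissible variance structure for this data")
    aic = {s: f[3] for s, f in fits.items()}
    best = min(aic, key=aic.get)
    beta, cov, var_obs, _, iters, groups = fits[best]

    n, p = x.shape
    stats_out = []
    for j, term in enumerate(terms):
        if term == "intercept":
            continue
        f_val = float(beta[j] ** 2 / cov[j, j])
        p_val = float(stats.f.sf(f_val, 1, n - p))
        stats_out.append(
            StatResult(kind="F", value=f_val, df=(1.0, float(n - p)), p=p_val, note=term)
        )
    group_var = pd.Series(var_obs).groupby(groups).first()
    return FGLSResult(
        params=pd.Series(beta, index=terms),
        stats=stats_out,
        variance_structure=best,
        aic_by_structure=aic,
        group_variances=group_var,
        n_iterations=iters,
    )


# ---------------------------------------------------------------------------
# Small inferential toolbox
# ---------------------------------------------------------------------------


def simple_regression(x: Iterable[float], y: Iterable[float]) -> RegressionResult:
    """Ordinary least-squares line with the overall F-test (df 1, n−2)."""
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if len(x) != len(y):
        raise ValidationError("x and y must be paired")
    if len(x) < 3:
        raise ValidationError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("predictor is constant")
    fit = stats.linregress(x, y)
    n = len(x)
    r2 = fit.rvalue**2
    if math.isclose(r2, 1.0):
        f_val, p_val = math.inf, 0.0
    else:
        f_val = r2 / (1 - r2) * (n - 2)
        p_val = float(stats.f.sf(f_val, 1, n - 2))
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        stat=StatResult(
            kind="F",
            value=float(f_val),
            df=(1.0, float(n - 2)),
            p=p_val,
            effect_size=float(r2),
            effect_kind="r_squared",
        ),
    )


def paired_t_cohens_d(a: Iterable[float], b: Iterable[float]) -> StatResult:
    """Paired t-test on a − b with Cohen's D = |mean(d)| / sd(d).

    A zero-variance difference with nonzero mean is flagged explicitly as an
    infinite t rather than raising (the direction is still informative).
    """
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if len(a) != len(b) or len(a) < 2:
        raise ValidationError("need equal-length paired vectors with n >= 2")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return StatResult("t", 0.0, (float(n - 1),), 1.0, 0.0, "cohen_d")
        return StatResult(
            "t",
            math.copysign(math.inf, mean),
            (float(n - 1),),
            0.0,
            math.inf,
            "cohen_d",
            note="zero-variance differences; t is infinite",
        )
    t = mean / (sd / math.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return StatResult("t", float(t), (float(n - 1),), p, abs(mean) / sd, "cohen_d")


def _signed_rank_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p for W+ by enumerating all 2^n sign assignments."""
    n = len(ranks)
    le = ge = 0
    total = 2**n
    # distribution of W+ via subset sums; n <= 12 keeps this at 4096 terms
    for signs in itertools.product((0, 1), repeat=n):
        w = float(np.dot(signs, ranks))
        le += w <= w_obs + 1e-12
        ge += w >= w_obs - 1e-12
    return min(1.0, 2.0 * min(le, ge) / total)


def wilcoxon_signed_rank(
    a: Iterable[float], b: Iterable[float], mode: str = "auto"
) -> StatResult:
    """Paired Wilcoxon signed-rank test with effect size r = |z| / √n.

    Zero differences are dropped (Wilcoxon's rule); ties in |d| get average
    ranks. ``mode='exact'`` enumerates all sign assignments (n ≤ 12 after
    dropping zeros), ``'normal-approx'`` uses the tie-corrected normal
    approximation with continuity correction; ``'auto'`` picks exact for
    small n. The z statistic (and hence r) is always reported from the
    normal approximation so the effect size is defined in both modes.
    """
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if len(a) != len(b):
        raise ValidationError("need paired vectors")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValidationError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    mean_w = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var_w <= 0:
        raise ValidationError("degenerate rank variance")
    # continuity correction toward the mean
    z = (w_plus - mean_w - 0.5 * np.sign(w_plus - mean_w)) / math.sqrt(var_w)
    if mode == "auto":
        mode = "exact" if n <= 12 else "normal-approx"
    if mode == "exact":
        if n > 12:
            raise ValidationError("exact mode enumerates 2^n signs; use n <= 12")
        p = _signed_rank_exact_p(ranks, w_plus)
    elif mode == "normal-approx":
        if n < 5:
            raise ValidationError("normal approximation needs n >= 5")
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return StatResult(
        kind="W",
        value=w_plus,
        df=(float(n),),
        p=p,
        effect_size=abs(z) / math.sqrt(n),
        effect_kind="r",
        note=f"z={z:.4f}; mode={mode}",
    )
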