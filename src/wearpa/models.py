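"""Random-intercept multilevel models with within/between decomposition.

Days are nested within participants.  Every day-level weather predictor
enters as a pair: a *daily* (person-centered deviation) term carrying the
within-person effect and an *overall* (grand-mean-centered person mean)
term carrying the between-person effect.  Age and self-rated health are
grand-mean-centered; sex (female = 1), freeze-thaw, tropical night,
weekend and the study-day index enter as-is.

Models are Gaussian linear mixed models with a participant random
intercept, estimated by REML (statsmodels ``MixedLM``).  Fixed-effect
confidence intervals and p-values are Wald/normal.  The intraclass
correlation is tau00 / (tau00 + sigma2) from an intercept-only model, and
marginal / conditional R-squared follow the variance-partition form

    R2_m = var_f / (var_f + tau00 + sigma2)
    R2_c = (var_f + tau00) / (var_f + tau00 + sigma2)

with var_f the sample variance of the fixed-effect linear predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "WEATHER_PAIRS",
    "DEFAULT_PREDICTORS",
    "MODEL_OUTCOMES",
    "ModelResult",
    "center_within_between",
    "build_design",
    "fit_random_intercept",
    "compute_icc",
    "compute_r2",
    "person_level_correlation",
    "power_simulation",
    "fit_all_models",
]

#: Day-level predictors decomposed into (daily, overall) pairs.
WEATHER_PAIRS = ["tmean", "precip", "snow", "daylight"]

#: Fixed-effect rows of every model, in reporting order.
DEFAULT_PREDICTORS = [
    *[f"{v}_{w}" for v in WEATHER_PAIRS for w in ("daily", "overall")],
    "freeze_thaw",
    "tropical_night",
    "study_day",
    "age_c",
    "sex_female",
    "health_c",
    "weekend",
]

#: The nine model outcomes, keyed by model number.
MODEL_OUTCOMES = {
    1: "lpa_min",
    2: "lpa_in_min",
    3: "lpa_out_min",
    4: "mvpa_min",
    5: "mvpa_in_min",
    6: "mvpa_out_min",
    7: "sb_min",
    8: "steps",
    9: "walk_out_min",
}

_Z975 = stats.norm.ppf(0.975)


@dataclass
class ModelResult:
    """Fixed effects with Wald CIs/p, variance components and fit metadata."""

    outcome: str
    fixed: pd.DataFrame  # index: term; columns: estimate, ci_low, ci_high, p
    sigma2: float
    tau00: float
    n_persons: int
    n_obs: int
    n_dropped: int
    r2_marginal: float
    r2_conditional: float
    singular: bool = False
    inference: str = "wald-normal"
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        """Table mirroring the published layout: one row per predictor plus
        variance components, group/observation counts and R-squared."""
        out = self.fixed.copy()
        meta = pd.DataFrame(
            {
                "estimate": [
                    self.sigma2,
                    self.tau00,
                    self.n_persons,
                    self.n_obs,
                    self.r2_marginal,
                    self.r2_conditional,
                ]
            },
            index=["sigma2", "tau00_id", "n_id", "observations", "r2_marginal", "r2_conditional"],
        )
        return pd.concat([out, meta])


def center_within_between(
    values: pd.Series, groups: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Split a day-level variable into within- and between-person parts.

    Returns ``(daily, overall)`` aligned with the input: ``daily`` is the
    deviation from the person mean (sums to zero within each person);
    ``overall`` is the person mean centered on the unweighted grand mean
    of person means.
    """
    values = pd.Series(np.asarray(values, float), index=groups.index)
    person_mean = values.groupby(groups).transform("mean")
    daily = values - person_mean
    grand = values.groupby(groups).mean().mean()  # unweighted over persons
    overall = person_mean - grand
    return daily.rename("daily"), overall.rename("overall")


def build_design(
    table: pd.DataFrame, outcome: str, predictors: list[str] | None = None
) -> tuple[pd.DataFrame, int]:
    """Complete-case design matrix for one model.

    Rows missing the outcome or any raw predictor are dropped first;
    centering is then computed on the analysis sample.  Returns the design
    frame (outcome, predictors, participant_id) and the number of rows
    dropped.
    """
    predictors = predictors or DEFAULT_PREDICTORS
    raw_needed = {"participant_id", outcome, "freeze_thaw", "tropical_night",
                  "study_day", "age", "sex_female", "health", "weekend"}
    raw_needed |= {v for v in WEATHER_PAIRS if any(p.startswith(v) for p in predictors)}
    cols = [c for c in raw_needed if c in table.columns]
    missing = raw_needed - set(cols)
    if missing:
        raise KeyError(f"analysis table lacks columns {sorted(missing)}")
    sub = table[cols].copy()
    n0 = len(sub)
    sub = sub.dropna()
    n_dropped = n0 - len(sub)

    design = pd.DataFrame({"participant_id": sub["participant_id"], outcome: sub[outcome]})
    g = sub["participant_id"]
    for v in WEATHER_PAIRS:
        daily, overall = center_within_between(sub[v], g)
        design[f"{v}_daily"] = daily
        design[f"{v}_overall"] = overall
    design["freeze_thaw"] = sub["freeze_thaw"].astype(float)
    design["tropical_night"] = sub["tropical_night"].astype(float)
    design["study_day"] = sub["study_day"].astype(float)
    design["age_c"] = sub["age"] - sub.groupby("participant_id")["age"].first().mean()
    design["sex_female"] = sub["sex_female"].astype(float)
    design["health_c"] = sub["health"] - sub.groupby("participant_id")["health"].first().mean()
    design["weekend"] = sub["weekend"].astype(float)
    return design.reset_index(drop=True), n_dropped


def _wald_frame(params, bse, names) -> pd.DataFrame:
    est = np.asarray(params, float)
    se = np.asarray(bse, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, est / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "estimate": est,
            "ci_low": est - _Z975 * se,
            "ci_high": est + _Z975 * se,
            "p": p,
        },
        index=names,
    )


def fit_random_intercept(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str] | None = None,
    design: pd.DataFrame | None = None,
    n_dropped: int = 0,
) -> ModelResult:
    """Fit one random-intercept model by REML.

    ``table`` is the analysis table (see ``weather.nearest_station_merge``);
    pass ``design`` to skip the internal :func:`build_design` call.  A
    near-zero intercept variance is reported with ``singular=True``, never
    raised.
    """
    predictors = predictors or DEFAULT_PREDICTORS
    if design is None:
        design, n_dropped = build_design(table, outcome, predictors)
    y = design[outcome].to_numpy(float)
    # a predictor with no variation in the analysis sample (e.g. no
    # tropical night fell inside any window) is unidentified: excluded
    # from the fit, reported as NaN
    constant = [p_ for p_ in predictors if np.std(design[p_].to_numpy(float)) == 0.0]
    active = [p_ for p_ in predictors if p_ not in constant]
    names = ["Intercept", *active]
    X = pd.DataFrame({"Intercept": np.ones(len(design))})
    for p_ in active:
        X[p_] = design[p_].to_numpy(float)
    groups = design["participant_id"].to_numpy()
    n_persons = len(np.unique(groups))

    if len(design) == 0 or np.var(y) == 0.0:
        # Degenerate outcome: nothing to estimate.
        all_names = ["Intercept", *predictors]
        fixed = _wald_frame(np.zeros(len(all_names)), np.zeros(len(all_names)), all_names)
        if len(design):
            fixed.loc["Intercept", "estimate"] = float(y[0]) if len(y) else 0.0
        return ModelResult(
            outcome=outcome, fixed=fixed, sigma2=0.0, tau00=0.0,
            n_persons=n_persons, n_obs=len(design), n_dropped=n_dropped,
            r2_marginal=0.0, r2_conditional=0.0, singular=True, converged=True,
        )

    Xmat = X.to_numpy(float)
    if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
        raise ValueError(
            f"design for {outcome!r} is rank deficient "
            f"({n_persons} persons cannot identify the person-level terms)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups)
        res = model.fit(reml=True)

    k = len(names)
    fixed = _wald_frame(res.params[:k], res.bse[:k], names)
    fixed = fixed.reindex(["Intercept", *predictors])  # NaN rows for constants
    sigma2 = float(res.scale)
    tau00 = float(np.asarray(res.cov_re)[0, 0])
    singular = tau00 < 1e-8 * (sigma2 + tau00)
    var_fixed = float(np.var(X.to_numpy() @ np.asarray(res.params[:k]), ddof=1))
    r2m, r2c = compute_r2(sigma2, tau00, var_fixed)
    return ModelResult(
        outcome=outcome,
        fixed=fixed,
        sigma2=sigma2,
        tau00=tau00,
        n_persons=n_persons,
        n_obs=len(design),
        n_dropped=n_dropped,
        r2_marginal=r2m,
        r2_conditional=r2c,
        singular=singular,
        converged=bool(res.converged),
    )


def compute_icc(table: pd.DataFrame, outcome: str) -> float:
    """Intraclass correlation from an unconditional (intercept-only) model."""
    sub = table[["participant_id", outcome]].dropna()
    y = sub[outcome].to_numpy(float)
    if len(sub) == 0 or np.var(y) == 0.0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MixedLM(y, np.ones((len(sub), 1)), groups=sub["participant_id"].to_numpy()).fit(
            reml=True
        )
    tau00 = float(np.asarray(res.cov_re)[0, 0])
    sigma2 = float(res.scale)
    return tau00 / (tau00 + sigma2)


def compute_r2(sigma2: float, tau00: float, fixed_effect_variance: float) -> tuple[float, float]:
    """Marginal and conditional R² from the variance partition."""
    denom = fixed_effect_variance + tau00 + sigma2
    if denom <= 0:
        return 0.0, 0.0
    return fixed_effect_variance / denom, (fixed_effect_variance + tau00) / denom


def person_level_correlation(
    table: pd.DataFrame, x: str, y: str, kind: str = "pearson"
) -> tuple[float, float]:
    """Correlation between person-level means of two variables.

    ``kind="pearson"`` for two continuous variables, ``"point_biserial"``
    when ``x`` is dichotomous (the two coincide numerically; the name
    records intent).  Returns ``(r, two-sided p)``.
    """
    if kind not in ("pearson", "point_biserial"):
        raise ValueError(f"unknown correlation kind {kind!r}")
    means = table.groupby("participant_id")[[x, y]].mean().dropna()
    if kind == "point_biserial":
        r, p = stats.pointbiserialr(means[x], means[y])
    else:
        r, p = stats.pearsonr(means[x], means[y])
    return float(r), float(p)


def power_simulation(
    effect_size: float,
    level: str,
    n_persons: int,
    n_days: int,
    icc: float,
    reps: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Simulation-based power for a single within- or between-person effect.

    The outcome has unit total variance split as ``icc`` between persons
    and ``1 - icc`` within; the predictor is standard normal at the stated
    level (``"within"``: day-level, person-centered; ``"between"``:
    person-level, grand-mean-centered).  ``effect_size`` is the slope per
    SD of the predictor, on the outcome scale.  Returns the fraction of
    replicates whose Wald p-value falls below ``alpha``.
    """
    if level not in ("within", "between"):
        raise ValueError(f"level must be 'within' or 'between', got {level!r}")
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(n_persons), n_days)
    hits = 0
    for _ in range(reps):
        if level == "within":
            x = rng.standard_normal(n_persons * n_days)
            x = x - x.reshape(n_persons, n_days).mean(axis=1)[groups]
        else:
            x = rng.standard_normal(n_persons)
            x = (x - x.mean())[groups]
        u = rng.standard_normal(n_persons) * np.sqrt(icc)
        e = rng.standard_normal(n_persons * n_days) * np.sqrt(1.0 - icc)
        yv = effect_size * x + u[groups] + e
        X = np.column_stack([np.ones_like(x), x])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(yv, X, groups=groups).fit(reml=True)
        se = res.bse[1]
        z = res.params[1] / se if se > 0 else 0.0
        if 2.0 * stats.norm.sf(abs(z)) < alpha:
            hits += 1
    return hits / reps


def fit_all_models(table: pd.DataFrame) -> dict[int, ModelResult]:
    """Fit the nine outcome models on one analysis table."""
    return {
        k: fit_random_intercept(table, outcome)
        for k, outcome in MODEL_OUTCOMES.items()
        if outcome in table.columns
    }
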