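"""Mixed-effects analysis recipes and Monte-Carlo power simulation.

Linear mixed models (random intercept per participant, REML) are fitted
with statsmodels' MixedLM; logistic mixed models with its Laplace/MAP
mixed GLM under wide priors.  This module owns everything around the
fits: model specification, Wald intervals, standardized betas and their
effect-size labels, marginal/conditional R-squared by variance
decomposition, Holm-corrected follow-up contrasts, and the power
simulation used for sample-size planning.

p-values for fixed effects use the normal (Wald) approximation, which
matches large-sample reporting; small-sample degrees-of-freedom
corrections are deliberately not applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.numdiff import approx_hess
from statsmodels.tools.sm_exceptions import ConvergenceWarning

LATENT_RESID_VAR = np.pi ** 2 / 3   # logistic latent-scale residual variance


class ModelError(ValueError):
    pass


@dataclass
class ModelFit:
    """A fitted mixed-model summary in reporting form."""

    formula: str
    kind: str                       # 'linear' | 'logistic'
    params: pd.Series               # fixed-effect coefficients
    conf_int: pd.DataFrame          # columns 'lower', 'upper' (95%)
    pvalues: pd.Series
    std_beta: pd.Series
    effect_labels: pd.Series        # weak / moderate / strong
    var_random: float
    var_resid: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_groups: int
    singular: bool = False
    notes: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.params, "ci_low": self.conf_int["lower"],
            "ci_high": self.conf_int["upper"], "p": self.pvalues,
            "std_beta": self.std_beta, "effect": self.effect_labels,
        })


def effect_label(std_beta: float) -> str:
    """Effect-size band for a standardized beta: the conventional r-like
    cut-offs (<0.2 weak, 0.2-0.5 moderate, >0.5 strong; boundaries round up)."""
    a = abs(std_beta)
    if a < 0.2:
        return "weak"
    if a <= 0.5:
        return "moderate"
    return "strong"


def standardized_betas(params: pd.Series, design: pd.DataFrame,
                       outcome: np.ndarray, kind: str = "linear",
                       var_random: float = 0.0) -> pd.Series:
    """std beta = b * SD(predictor) / SD(outcome), full-sample SDs.

    Interaction terms are standardized from their realized product column.
    For logistic models the outcome SD is taken on the latent scale:
    sqrt(var(X*b) + var_random + pi^2/3), a documented approximation.
    """
    if kind == "logistic":
        eta = design.to_numpy() @ params.to_numpy()
        sd_y = float(np.sqrt(np.var(eta) + var_random + LATENT_RESID_VAR))
    else:
        sd_y = float(np.std(outcome, ddof=1))
    if sd_y == 0 or not np.isfinite(sd_y):
        raise ModelError("outcome has zero variance; cannot standardize")
    out = {}
    for name, b in params.items():
        if name.lower() in ("intercept", "const"):
            out[name] = np.nan
            continue
        sd_x = float(np.std(design[name].to_numpy(), ddof=1))
        out[name] = b * sd_x / sd_y
    return pd.Series(out)


def r_squared(var_fixed: float, var_random: float, var_resid: float
              ) -> tuple[float, float]:
    """(marginal, conditional) R^2 by variance decomposition.

    Marginal: fixed-effect variance over total; conditional adds the
    random-intercept variance to the numerator.
    """
    total = var_fixed + var_random + var_resid
    if total <= 0:
        return 0.0, 0.0
    return var_fixed / total, (var_fixed + var_random) / total


def _finalize(formula: str, kind: str, data: pd.DataFrame, outcome: str,
              params: pd.Series, cov_or_sd, var_random: float, var_resid: float,
              n_groups: int, singular: bool, notes: list[str]) -> ModelFit:
    design = patsy.dmatrix(formula.split("~", 1)[1], data, return_type="dataframe")
    design = design[list(params.index)]
    if isinstance(cov_or_sd, pd.Series):   # standard errors
        se = cov_or_sd
    else:
        se = pd.Series(np.sqrt(np.diag(cov_or_sd)), index=params.index)
    z = params / se
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=params.index)
    ci = pd.DataFrame({
        "lower": params - stats.norm.ppf(0.975) * se,
        "upper": params + stats.norm.ppf(0.975) * se,
    })
    y = data[outcome].to_numpy(float)
    std = standardized_betas(params, design, y, kind, var_random)
    labels = std.map(lambda v: "n/a" if np.isnan(v) else effect_label(v))
    eta = design.to_numpy() @ params.to_numpy()
    var_fixed = float(np.var(eta))
    r2m, r2c = r_squared(var_fixed, var_random, var_resid)
    return ModelFit(
        formula=formula, kind=kind, params=params, conf_int=ci, pvalues=pvals,
        std_beta=std, effect_labels=labels, var_random=var_random,
        var_resid=var_resid, r2_marginal=r2m, r2_conditional=r2c,
        n_obs=len(data), n_groups=n_groups, singular=singular, notes=notes,
    )


def fit_lmm(formula: str, data: pd.DataFrame, group_col: str = "participant"
            ) -> ModelFit:
    """Random-intercept linear mixed model, REML, Wald inference."""
    outcome = formula.split("~")[0].strip()
    data = data.dropna(subset=_term_columns(formula, data)).reset_index(drop=True)
    if data[group_col].nunique() < 2:
        raise ModelError("need at least 2 participants")
    if np.std(data[outcome].to_numpy(float)) == 0:
        raise ModelError(f"outcome {outcome!r} has zero variance")
    notes, singular = [], False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = MixedLM.from_formula(formula, data, groups=data[group_col])
        res = model.fit(reml=True)
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                singular = True
                notes.append(str(w.message))
    params = res.fe_params
    cov = res.cov_params().loc[params.index, params.index]
    var_random = float(res.cov_re.iloc[0, 0])
    return _finalize(formula, "linear", data, outcome, params, cov,
                     var_random, float(res.scale), data[group_col].nunique(),
                     singular, notes)


def _ghq_logistic_loglik(beta: np.ndarray, log_sd: float, X: np.ndarray,
                         y: np.ndarray, gidx: np.ndarray, n_groups: int,
                         nodes: np.ndarray, weights: np.ndarray) -> float:
    """Marginal log-likelihood of a random-intercept logistic model.

    The random intercept is integrated out per group by Gauss-Hermite
    quadrature: with u = sqrt(2)*sd*t, the Gaussian integral becomes a
    weighted sum over the Hermite nodes.
    """
    sd = np.exp(log_sd)
    eta0 = X @ beta
    # per-observation log p(y | eta) at every node: (n_obs, n_nodes)
    eta = eta0[:, None] + np.sqrt(2.0) * sd * nodes[None, :]
    ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
    per_group = np.zeros((n_groups, len(nodes)))
    np.add.at(per_group, gidx, ll_obs)
    return float(np.sum(special.logsumexp(per_group + np.log(weights)[None, :],
                                          axis=1)) - n_groups * 0.5 * np.log(np.pi))


def fit_logistic_mm(formula: str, data: pd.DataFrame,
                    group_col: str = "participant",
                    n_quad: int = 31) -> ModelFit:
    """Random-intercept logistic mixed model by Gauss-Hermite ML.

    The marginal likelihood is maximized over the fixed effects and the
    log random-intercept SD; Wald standard errors come from the inverse
    numerical Hessian at the optimum.  Agreement with lme4's ``glmer`` is
    exercised in the test suite.
    """
    outcome = formula.split("~")[0].strip()
    data = data.dropna(subset=_term_columns(formula, data)).reset_index(drop=True)
    y = data[outcome].to_numpy(float)
    if y.min() == y.max():
        raise ModelError(f"outcome {outcome!r} is constant (complete separation)")
    design = patsy.dmatrix(formula.split("~", 1)[1], data, return_type="dataframe")
    X = design.to_numpy()
    codes, uniques = pd.factorize(data[group_col])
    n_groups = len(uniques)
    if n_groups < 2:
        raise ModelError("need at least 2 participants")
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    def nll(theta: np.ndarray) -> float:
        return -_ghq_logistic_loglik(theta[:-1], theta[-1], X, y, codes,
                                     n_groups, nodes, weights)

    k = X.shape[1]
    theta0 = np.zeros(k + 1)
    theta0[0] = special.logit(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    res = optimize.minimize(nll, theta0, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 500})
    notes: list[str] = []
    if not res.success:
        notes.append(f"optimizer: {res.message}")
    hess = approx_hess(res.x, nll)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        raise ModelError("singular Hessian in logistic mixed model") from None
    se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    params = pd.Series(res.x[:k], index=list(design.columns))
    se = pd.Series(se_all[:k], index=params.index)
    sd_u = float(np.exp(res.x[-1]))
    return _finalize(formula, "logistic", data, outcome, params, se,
                     sd_u ** 2, LATENT_RESID_VAR, n_groups,
                     not res.success, notes)


def _term_columns(formula: str, data: pd.DataFrame) -> list[str]:
    rhs = formula.replace("~", "+").replace("*", "+").replace(":", "+")
    names = {t.strip() for t in rhs.split("+")}
    return [c for c in data.columns if c in names]


# ---------------------------------------------------------------------------
# the concrete model specifications


def fit_condition_model(probe_table: pd.DataFrame, outcome: str) -> ModelFit:
    """outcome ~ pressure * feedback + (1 | participant), REML.

    ``outcome`` is one of 'pof', 'cof', 'anxiety'; pressure/feedback are
    0/1 indicators with low/low as reference.
    """
    return fit_lmm(f"{outcome} ~ pressure * feedback", probe_table)


def fit_appraisal_model(probe_table: pd.DataFrame) -> ModelFit:
    """anxiety ~ pof * cof + (1 | participant), REML."""
    for col in ("pof", "cof"):
        if np.std(probe_table[col].to_numpy(float)) == 0:
            raise ModelError(f"predictor {col!r} has zero variance")
    return fit_lmm("anxiety ~ pof * cof", probe_table)


def fit_outcome_model(table: pd.DataFrame, outcome: str) -> ModelFit:
    """Trial outcome ~ anxiety + pof * cof + (1 | participant).

    Linear for the continuous outcomes (bounce fixation pitch/duration,
    peak swing velocity); logistic for binary interception.
    """
    formula = f"{outcome} ~ anxiety + pof * cof"
    if outcome == "intercepted":
        tab = table.copy()
        tab["intercepted"] = tab["intercepted"].astype(float)
        return fit_logistic_mm(formula, tab)
    return fit_lmm(formula, table)


def fit_error_dependency_model(trial_table: pd.DataFrame) -> ModelFit:
    """intercepted ~ prior_errors * carried_anxiety + (1 | participant).

    Rows without a carried-forward anxiety value (before a block's first
    probe) are dropped.
    """
    tab = trial_table.dropna(subset=["carried_anxiety", "intercepted"]).copy()
    tab["intercepted"] = tab["intercepted"].astype(float)
    return fit_logistic_mm("intercepted ~ prior_errors * carried_anxiety", tab)


def reproduce_reported_models(probe_table: pd.DataFrame,
                              trial_table: pd.DataFrame | None = None,
                              winsorize_outliers: bool = True
                              ) -> dict[str, ModelFit]:
    """Run the complete mixed-model suite on an assembled dataset.

    Intended for re-analysis of a deposited dataset (after adapting its
    column layout with the trialio column-mapping hooks) or of a full
    synthetic study.  Continuous outcomes are winsorized at 3 SDs within
    condition before fitting.
    """
    from .preprocess import winsorize
    probe = probe_table.copy()
    cond = probe["pressure"].astype(str) + ":" + probe["feedback"].astype(str)
    if winsorize_outliers:
        for col in ("pof", "cof", "anxiety", "bounce_fix_pitch",
                    "bounce_fix_duration", "peak_swing_velocity"):
            if col in probe.columns:
                probe[col] = winsorize(probe[col], cond)
    import logging
    log = logging.getLogger("vrintercept")
    fits: dict[str, ModelFit] = {}

    def _try(name, fn, *args):
        try:
            fits[name] = fn(*args)
        except ModelError as err:
            log.warning("model %s not estimable: %s", name, err)

    for outcome in ("pof", "cof", "anxiety"):
        _try(f"condition_{outcome}", fit_condition_model, probe, outcome)
    _try("appraisal_anxiety", fit_appraisal_model, probe)
    for outcome in ("bounce_fix_pitch", "bounce_fix_duration",
                    "peak_swing_velocity", "intercepted"):
        if outcome in probe.columns and probe[outcome].notna().sum() > 0:
            _try(f"outcome_{outcome}", fit_outcome_model,
                 probe.dropna(subset=[outcome]), outcome)
    if trial_table is not None and "carried_anxiety" in trial_table.columns:
        _try("error_dependency", fit_error_dependency_model, trial_table)
    return fits


# ---------------------------------------------------------------------------
# follow-ups


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="holm")[1]


def holm_followups(probe_table: pd.DataFrame, outcome: str,
                   contrasts: list[tuple[str, str, str, str]]) -> pd.DataFrame:
    """Paired t-tests on participant cell means, Holm-corrected.

    Each contrast is ``(label, within_factor_level_expr, level_a, level_b)``
    where the expression names the conditioning cell, e.g.
    ``("pressure @ feedback=high", "feedback == 1", "pressure", "0 vs 1")``
    is spelled as ``("label", "feedback == 1", "pressure", "pressure")`` —
    concretely: rows are filtered by the query, then participant means of
    ``outcome`` are compared between the two levels (0 and 1) of the named
    factor with a paired t-test.
    """
    rows = []
    for label, query, factor, _ in contrasts:
        sub = probe_table.query(query) if query else probe_table
        cell = sub.groupby(["participant", factor])[outcome].mean().unstack(factor)
        cell = cell.dropna()
        tstat, p = stats.ttest_rel(cell.iloc[:, 0], cell.iloc[:, 1])
        rows.append({"contrast": label, "t": float(tstat), "p_raw": float(p),
                     "n": len(cell)})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# power simulation


def simulate_power(
    effect: float,
    n_participants,
    obs_per_participant: int = 24,
    icc: float = 0.5,
    reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    focal: str = "feedback",
) -> pd.DataFrame:
    """Monte-Carlo power for the 2x2 probe-design condition model.

    For each sample size, datasets are simulated from the random-intercept
    truth (observations split evenly over the four pressure x feedback
    cells; total outcome variance 1 split by ``icc``), the condition model
    is fitted, and power is the fraction of replicates whose focal
    coefficient has p < ``alpha``.  ``effect`` is the standardized beta of
    the focal (feedback) effect: the raw coefficient is
    effect * SD(y) / SD(indicator) with SD(indicator) = 0.5.

    Returns a DataFrame with columns n, power, mc_se.
    """
    if reps < 50:
        raise ModelError("reps must be >= 50 for a usable power estimate")
    ns = [n_participants] if np.isscalar(n_participants) else list(n_participants)
    rng = np.random.default_rng(seed)
    var_u, var_e = icc, 1.0 - icc
    beta = effect * 1.0 / 0.5
    m = obs_per_participant
    if m % 4:
        raise ModelError("obs_per_participant must divide evenly into 4 cells")
    rows = []
    for n in ns:
        pid = np.repeat(np.arange(n), m)
        press = np.tile(np.repeat([0, 1], m // 2), n)
        feed = np.tile(np.tile(np.repeat([0, 1], m // 4), 2), n)
        hits = 0
        for _ in range(reps):
            u = rng.normal(0, np.sqrt(var_u), n)[pid]
            y = beta * feed + u + rng.normal(0, np.sqrt(var_e), n * m)
            df = pd.DataFrame({"y": y, "pressure": press, "feedback": feed,
                               "participant": pid})
            fit = fit_lmm("y ~ pressure * feedback", df)
            hits += fit.pvalues[focal] < alpha
        power = hits / reps
        rows.append({"n": n, "power": power,
                     "mc_se": float(np.sqrt(power * (1 - power) / reps))})
    return pd.DataFrame(rows)
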