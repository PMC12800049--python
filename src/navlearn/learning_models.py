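"""Statistical models of learning in the two-path navigation task.

Linear mixed-effects models relate the pre-guard lateral shift to an
exponential-decay transform of trial number (``exp(-trial)``), with
participant random intercepts (optionally random slopes).  Logistic
mixed-effects models describe the binary early-commitment choices of the
forced-choice experiment; a saturating exponential learning curve
``a - b * exp(-c * t)`` is fitted as an alternative and compared by AIC.
Marginal and conditional R-squared follow the variance-decomposition
convention for mixed models (fixed effects alone vs fixed + random).

Linear mixed models delegate to statsmodels ``MixedLM``; the logistic
random-intercept model is fitted here by maximum likelihood with
Gauss-Hermite quadrature over the random effect.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


@dataclass
class ModelFit:
    """A fitted model: coefficient table plus fit diagnostics.

    ``params``/``se``/``zvalues``/``pvalues`` are pandas Series indexed
    by term; ``conf_int`` a DataFrame with columns (lower, upper);
    ``std_beta`` standardized coefficients (beta * SD(x) / SD(y) on the
    estimation sample).  p-values use the normal approximation on z.
    """
    formula: str
    params: pd.Series
    se: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    std_beta: pd.Series
    aic: float
    marginal_r2: float | None = None
    conditional_r2: float | None = None
    converged: bool = True
    singular: bool = False
    flags: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame({
            "estimate": self.params, "se": self.se, "z": self.zvalues,
            "p": self.pvalues, "ci_low": self.conf_int["lower"],
            "ci_high": self.conf_int["upper"], "std_beta": self.std_beta,
        })
        return tab

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "coefficients": self.summary().to_dict(orient="index"),
            "aic": self.aic,
            "marginal_r2": self.marginal_r2,
            "conditional_r2": self.conditional_r2,
            "converged": self.converged,
            "singular": self.singular,
            "flags": list(self.flags),
            "extra": {k: v for k, v in self.extra.items()
                      if isinstance(v, (int, float, str, bool, type(None)))},
        }


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

JOIN_KEYS = ["participant_id", "block_index", "trial_in_block"]


def build_trial_table(trials: pd.DataFrame,
                      trial_metrics: pd.DataFrame | None = None,
                      gaze_metrics: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format analysis table, one row per trial.

    Inner-joins the trial, movement-metric and gaze-metric tables on
    (participant, block, trial) and derives ``expdecay = exp(-trial)``
    (trial indexed from 1) and ``block_position`` — the order of the
    block among that participant's *biased* blocks (NaN for control).
    Duplicate keys are rejected.
    """
    table = trials.copy()
    for other, name in ((trial_metrics, "trial_metrics"), (gaze_metrics, "gaze_metrics")):
        if other is None:
            continue
        dup_cols = [c for c in other.columns
                    if c in table.columns and c not in JOIN_KEYS]
        other = other.drop(columns=dup_cols)
        if other.duplicated(JOIN_KEYS).any() or table.duplicated(JOIN_KEYS).any():
            raise ValueError(f"duplicate (participant, block, trial) keys joining {name}")
        before = len(table)
        table = table.merge(other, on=JOIN_KEYS, how="inner")
        if len(table) == 0 and before > 0:
            logger.warning("join with %s produced an empty table", name)
    table["expdecay"] = np.exp(-table["trial_in_block"].astype(float))
    biased = table["condition"] != "control"
    pos = (table.loc[biased, ["participant_id", "block_index"]]
           .drop_duplicates()
           .sort_values(["participant_id", "block_index"]))
    pos["block_position"] = pos.groupby("participant_id").cumcount() + 1
    table = table.merge(pos, on=["participant_id", "block_index"], how="left")
    if "correct" in table.columns:
        table["correct"] = table["correct"].map(
            lambda v: np.nan if v is None or (isinstance(v, float) and np.isnan(v))
            else float(bool(v)))
    return table


# ---------------------------------------------------------------------------
# linear mixed models (statsmodels MixedLM)
# ---------------------------------------------------------------------------

def _std_beta(params: pd.Series, data: pd.DataFrame, outcome: str) -> pd.Series:
    sy = float(np.std(data[outcome].to_numpy(), ddof=1))
    out = {}
    for term in params.index:
        if term in data.columns and sy > 0:
            sx = float(np.std(data[term].to_numpy(), ddof=1))
            out[term] = params[term] * sx / sy
        else:
            out[term] = np.nan
    return pd.Series(out)


def _mixedlm_r2(result, data: pd.DataFrame) -> tuple[float, float]:
    """Marginal/conditional R2 by variance decomposition.

    var_fixed is the variance of the fixed-effect linear predictor;
    var_random averages z_i' G z_i over observations (random intercept:
    simply the intercept variance); var_resid is the residual scale.
    """
    fe = result.model.exog @ result.fe_params
    var_f = float(np.var(fe))
    G = result.cov_re.to_numpy()
    Z = result.model.exog_re
    if Z is None:
        var_r = 0.0
    else:
        var_r = float(np.mean(np.einsum("ij,jk,ik->i", Z, G, Z)))
    var_e = float(result.scale)
    tot = var_f + var_r + var_e
    return var_f / tot, (var_f + var_r) / tot


def fit_mixed_linear(data: pd.DataFrame, formula: str, outcome: str,
                     re_formula: str | None = None,
                     groups: str = "participant_id") -> ModelFit:
    """Random-intercept (optionally random-slope) linear mixed model.

    Wraps statsmodels MixedLM; adds standardized coefficients, marginal
    and conditional R-squared, and singularity/degeneracy flags.
    """
    data = data.dropna(subset=[outcome]).copy()
    flags = []
    if data[outcome].nunique() <= 1:
        raise ValueError("outcome has no variance: degenerate fit")
    if data[groups].nunique() < 2:
        raise ValueError("need >= 2 participants for a mixed model")
    model = smf.mixedlm(formula, data, groups=data[groups], re_formula=re_formula)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True, method=["lbfgs", "powell"])
        converged = bool(result.converged)
        re_var = np.diag(result.cov_re.to_numpy())
        params = result.fe_params
        se = result.bse_fe
        aic_val = result.aic
        m_r2, c_r2 = _mixedlm_r2(result, data)
    singular = bool(np.any(re_var < 1e-8 * result.scale))
    if singular:
        flags.append("singular fit: a random-effect variance is ~0; "
                     "consider dropping the random slope")
    z = params / se
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=params.index)
    ci = pd.DataFrame({"lower": params - 1.96 * se, "upper": params + 1.96 * se})
    return ModelFit(formula=formula, params=params, se=se, zvalues=z, pvalues=p,
                    conf_int=ci, std_beta=_std_beta(params, data, outcome),
                    aic=float(aic_val) if aic_val is not None else np.nan,
                    marginal_r2=m_r2, conditional_r2=c_r2, converged=converged,
                    singular=singular, flags=flags,
                    extra={"n_obs": int(len(data)),
                           "n_groups": int(data[groups].nunique()),
                           "scale": float(result.scale)})


def fit_expdecay_mixed(table: pd.DataFrame, random_slopes: bool = False,
                       outcome: str = "normalized_x") -> ModelFit:
    """Pre-guard lateral shift ~ exp(-trial), biased blocks only.

    A negative slope means stronger anticipatory shifts in later trials
    (expdecay is large early and near zero late).  ``random_slopes``
    adds a per-participant random slope for expdecay.
    """
    data = table[table["condition"] != "control"].copy()
    if "expdecay" not in data.columns:
        data["expdecay"] = np.exp(-data["trial_in_block"].astype(float))
    re_formula = "~expdecay" if random_slopes else None
    return fit_mixed_linear(data, f"{outcome} ~ expdecay", outcome, re_formula)


def fit_control_trial_model(table: pd.DataFrame,
                            outcome: str = "normalized_x") -> ModelFit:
    """Trial-number model on control blocks (baseline drift check)."""
    data = table[table["condition"] == "control"]
    return fit_mixed_linear(data, f"{outcome} ~ trial_in_block", outcome)


def fit_block_position_model(table: pd.DataFrame, random_slopes: bool = False,
                             outcome: str = "normalized_x") -> ModelFit:
    """Within-block learning x block order (biased blocks only).

    Fixed effects: expdecay, block_position (order among biased blocks)
    and their interaction; random intercept per participant.
    """
    data = table[(table["condition"] != "control")].copy()
    if "expdecay" not in data.columns:
        data["expdecay"] = np.exp(-data["trial_in_block"].astype(float))
    if "block_position" not in data.columns:
        pos = (data[["participant_id", "block_index"]].drop_duplicates()
               .sort_values(["participant_id", "block_index"]))
        pos["block_position"] = pos.groupby("participant_id").cumcount() + 1
        data = data.merge(pos, on=["participant_id", "block_index"])
    data = data.dropna(subset=["block_position"])
    if data.groupby("participant_id")["block_position"].nunique().max() < 2:
        raise ValueError("block_position inestimable: one biased block per participant")
    re_formula = "~expdecay" if random_slopes else None
    return fit_mixed_linear(data, f"{outcome} ~ expdecay * block_position",
                            outcome, re_formula)


def fit_gaze_models(table: pd.DataFrame) -> dict[str, ModelFit]:
    """Mixed models for saccade rate and fixation dispersion.

    Fixed effects: trial number within block, condition (biased vs
    control), block number, and the trial x condition and trial x block
    interactions; random intercept per participant.
    """
    if table.groupby(["participant_id", "block_index"])["trial_in_block"].nunique().max() < 2:
        raise ValueError("within-block trial effect inestimable: single-trial blocks")
    data = table.copy()
    data["biased"] = (data["condition"] != "control").astype(float)
    data["block_number"] = data["block_index"].astype(float)
    out = {}
    for metric in ("saccade_rate", "fixation_dispersion"):
        formula = (f"{metric} ~ trial_in_block + biased + block_number"
                   " + trial_in_block:biased + trial_in_block:block_number")
        out[metric] = fit_mixed_linear(data, formula, metric)
    return out


# ---------------------------------------------------------------------------
# logistic mixed model (Gauss-Hermite quadrature)
# ---------------------------------------------------------------------------

def _glmm_nll(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
              group_idx: np.ndarray, n_groups: int,
              nodes: np.ndarray, weights: np.ndarray) -> float:
    """Negative marginal log-likelihood of a random-intercept logistic model.

    The random intercept u ~ N(0, sigma^2) is integrated out per group
    with Gauss-Hermite quadrature (physicists' rule: int f(u) phi(u) du
    = sum_q w_q/sqrt(pi) f(sqrt(2) sigma x_q)).
    """
    k = X.shape[1]
    beta = theta[:k]
    sigma = np.exp(theta[k])
    eta = X @ beta
    # log p(y_ij | u) summed per group, for each node
    offsets = np.sqrt(2.0) * sigma * nodes  # (Q,)
    # (n, Q) matrix of per-observation log-likelihood at each node
    lin = eta[:, None] + offsets[None, :]
    ll_obs = y[:, None] * lin - np.logaddexp(0.0, lin)
    ll_group = np.zeros((n_groups, nodes.size))
    np.add.at(ll_group, group_idx, ll_obs)
    log_w = np.log(weights / np.sqrt(np.pi))
    return -float(special.logsumexp(ll_group + log_w[None, :], axis=1).sum())


def fit_logistic_mixed(data: pd.DataFrame, outcome: str, predictors: list[str],
                       groups: str = "participant_id", n_quad: int = 25) -> ModelFit:
    """Maximum-likelihood random-intercept logistic mixed model.

    Fixed effects ``predictors`` (an intercept is always included) on a
    binary ``outcome``; one Gaussian random intercept per ``groups``
    level, integrated by ``n_quad``-node Gauss-Hermite quadrature.
    Standard errors come from the numerical Hessian at the optimum.
    Complete separation is flagged (coefficients diverge).
    """
    data = data.dropna(subset=[outcome] + predictors).copy()
    y = data[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    X = np.column_stack([np.ones(len(data))] + [data[p].to_numpy(dtype=float)
                                                for p in predictors])
    names = ["Intercept"] + list(predictors)
    codes, _ = pd.factorize(data[groups])
    n_groups = int(codes.max()) + 1
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    flags = []

    # starting values from a plain GLM
    import statsmodels.api as sm
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            beta0 = np.asarray(glm.params)
        except Exception:
            beta0 = np.zeros(X.shape[1])
    theta0 = np.concatenate([beta0, [np.log(0.5)]])

    def nll(theta):
        return _glmm_nll(theta, y, X, codes, n_groups, nodes, weights)

    with np.errstate(over="ignore"):
        res = optimize.minimize(nll, theta0, method="BFGS",
                                options={"maxiter": 500, "gtol": 1e-6})
        if not res.success:
            res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                     options={"maxiter": 4000, "xatol": 1e-8,
                                              "fatol": 1e-8})
            if res2.fun <= res.fun:
                res = res2
    theta = res.x
    k = X.shape[1]
    if np.any(np.abs(theta[:k]) > 15):
        flags.append("possible complete separation: coefficient diverging")

    # numerical Hessian of the negative log-likelihood
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    dim = theta.size
    H = np.zeros((dim, dim))
    f0 = res.fun
    for i in range(dim):
        for j in range(i, dim):
            ei = np.zeros(dim); ei[i] = h[i]
            ej = np.zeros(dim); ej[j] = h[j]
            fpp = nll(theta + ei + ej)
            fpm = nll(theta + ei - ej)
            fmp = nll(theta - ei + ej)
            fmm = nll(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(dim, np.nan)
        flags.append("Hessian not invertible")

    params = pd.Series(theta[:k], index=names)
    se = pd.Series(se_all[:k], index=names)
    z = params / se
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
    ci = pd.DataFrame({"lower": params - 1.96 * se, "upper": params + 1.96 * se})
    sigma = float(np.exp(theta[k]))
    singular = sigma < 1e-4
    if singular:
        flags.append("singular fit: random-intercept variance ~0")
    # latent-scale variance decomposition (logistic residual pi^2/3)
    var_f = float(np.var(X @ theta[:k]))
    var_r = sigma ** 2
    var_e = np.pi ** 2 / 3
    tot = var_f + var_r + var_e
    sy = float(np.std(y, ddof=1))
    std_beta = {}
    for nm in names:
        if nm in data.columns and sy > 0:
            std_beta[nm] = params[nm] * float(np.std(data[nm], ddof=1)) / np.sqrt(tot)
        else:
            std_beta[nm] = np.nan
    aic = 2 * (k + 1) + 2 * res.fun
    return ModelFit(formula=f"{outcome} ~ {' + '.join(predictors)} + (1|{groups})",
                    params=params, se=se, zvalues=z, pvalues=p, conf_int=ci,
                    std_beta=pd.Series(std_beta), aic=float(aic),
                    marginal_r2=var_f / tot, conditional_r2=(var_f + var_r) / tot,
                    converged=bool(res.success or res.fun < np.inf),
                    singular=singular, flags=flags,
                    extra={"sigma_re": sigma, "nll": float(res.fun),
                           "n_obs": int(len(data)), "n_groups": n_groups})


def fit_logistic_learning(table: pd.DataFrame) -> ModelFit:
    """Binary correctness ~ trial number within block (biased blocks).

    The forced-choice experiment's primary learning model: a positive
    slope on trial number means increasing odds of choosing the open
    pathway as the block progresses.
    """
    data = table[(table["condition"] != "control")].copy()
    return fit_logistic_mixed(data, "correct", ["trial_in_block"])


# ---------------------------------------------------------------------------
# exponential learning curve
# ---------------------------------------------------------------------------

def fit_exponential_learning_curve(table: pd.DataFrame) -> ModelFit:
    """Saturating exponential accuracy curve a - b * exp(-c * t).

    Fitted to trial-level binary correctness by Bernoulli maximum
    likelihood (biased blocks), so its AIC is comparable with the
    logistic model's.  Flat data leave the rate c unidentified and are
    flagged.
    """
    data = table[(table["condition"] != "control")].dropna(subset=["correct"])
    t = data["trial_in_block"].to_numpy(dtype=float)
    y = data["correct"].to_numpy(dtype=float)
    if y.size < 10:
        raise ValueError("too few trials for the exponential curve")
    flags = []

    def nll(theta):
        a, b, c = theta
        p = np.clip(a - b * np.exp(-c * t), 1e-9, 1 - 1e-9)
        return -float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))

    # curve through overall accuracy as a flat start, plus a learning start
    acc = y.mean()
    starts = [np.array([max(acc, 0.6), 0.3, 0.4]),
              np.array([0.9, 0.45, 0.25]),
              np.array([acc, 0.0, 0.5])]
    best = None
    for s in starts:
        r = optimize.minimize(nll, s, method="L-BFGS-B",
                              bounds=[(0.01, 1.0), (0.0, 1.0), (1e-3, 5.0)])
        if best is None or r.fun < best.fun:
            best = r
    a, b, c = best.x
    if b < 1e-4 or b > 1 - 1e-4 or c <= 2e-3 or c >= 4.999:
        flags.append("rate parameter poorly identified (near-flat curve or "
                     "parameter at bound)")

    # SEs from the numerical Hessian
    h = 1e-5 * np.maximum(np.abs(best.x), 1.0)
    H = np.zeros((3, 3))
    for i in range(3):
        for j in range(i, 3):
            ei = np.zeros(3); ei[i] = h[i]
            ej = np.zeros(3); ej[j] = h[j]
            H[i, j] = H[j, i] = (nll(best.x + ei + ej) - nll(best.x + ei - ej)
                                 - nll(best.x - ei + ej) + nll(best.x - ei - ej)) \
                / (4 * h[i] * h[j])
    try:
        se_all = np.sqrt(np.clip(np.diag(np.linalg.inv(H)), 0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(3, np.nan)
    names = ["a", "b", "c"]
    params = pd.Series(best.x, index=names)
    se = pd.Series(se_all, index=names)
    z = params / se
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
    ci = pd.DataFrame({"lower": params - 1.96 * se, "upper": params + 1.96 * se})
    return ModelFit(formula="correct ~ a - b*exp(-c*trial)", params=params, se=se,
                    zvalues=z, pvalues=p, conf_int=ci,
                    std_beta=pd.Series(np.nan, index=names),
                    aic=float(2 * 3 + 2 * best.fun), converged=bool(best.success),
                    flags=flags, extra={"nll": float(best.fun), "n_obs": int(y.size)})


# ---------------------------------------------------------------------------
# threshold trial
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdEstimate:
    threshold: float
    trial: int | None  # None = not reached within max_trial

    @property
    def reached(self) -> bool:
        return self.trial is not None


def predict_threshold_trial(fit: ModelFit, threshold: float = 0.8,
                            max_trial: int = 20) -> ThresholdEstimate:
    """Smallest trial at which the logistic fit predicts accuracy >= threshold.

    Uses the fixed effects only (the group-level curve).  A non-positive
    slope that starts below threshold never reaches it.
    """
    b0 = float(fit.params.get("Intercept", np.nan))
    slope_terms = [t for t in fit.params.index if t != "Intercept"]
    if len(slope_terms) != 1:
        raise ValueError("threshold prediction needs a single-slope logistic fit")
    b1 = float(fit.params[slope_terms[0]])
    for t in range(1, max_trial + 1):
        pred = special.expit(b0 + b1 * t)
        if pred >= threshold:
            return ThresholdEstimate(threshold, t)
        if b1 <= 0:
            break
    return ThresholdEstimate(threshold, None)


# ---------------------------------------------------------------------------
# supporting classical tests
# ---------------------------------------------------------------------------

def one_sample_t(x, popmean: float = 0.0) -> dict:
    """One-sample t-test against ``popmean`` with mean and 95% CI."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need n >= 2")
    if np.std(x, ddof=1) == 0:
        return {"t": 0.0 if x[0] == popmean else np.inf, "p": np.nan,
                "mean": float(x.mean()), "df": x.size - 1,
                "flag": "zero variance"}
    r = stats.ttest_1samp(x, popmean)
    ci = r.confidence_interval(0.95)
    return {"t": float(r.statistic), "p": float(r.pvalue), "mean": float(x.mean()),
            "df": x.size - 1, "ci": (float(ci.low), float(ci.high))}


def welch_t(a, b) -> dict:
    """Welch's two-sample t-test with Cohen's d (pooled-SD standardizer)."""
    a = np.asarray(a, dtype=float); a = a[np.isfinite(a)]
    b = np.asarray(b, dtype=float); b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    r = stats.ttest_ind(a, b, equal_var=False)
    sp2 = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) \
        / (a.size + b.size - 2)
    d = (a.mean() - b.mean()) / np.sqrt(sp2) if sp2 > 0 else 0.0
    return {"t": float(r.statistic) if np.isfinite(r.statistic) else 0.0,
            "p": float(r.pvalue), "df": float(r.df), "cohens_d": float(d),
            "mean_a": float(a.mean()), "mean_b": float(b.mean())}


def kruskal_wallis(*groups) -> dict:
    """Kruskal-Wallis H-test across >= 2 groups."""
    clean = [np.asarray(g, dtype=float) for g in groups]
    clean = [g[np.isfinite(g)] for g in clean]
    if len(clean) < 2 or any(g.size < 2 for g in clean):
        raise ValueError("need >= 2 groups with n >= 2")
    r = stats.kruskal(*clean)
    return {"H": float(r.statistic), "p": float(r.pvalue),
            "df": len(clean) - 1}


def bootstrap_mean_ci(x, n_boot: int = 2000, alpha: float = 0.05, seed=0) -> dict:
    """Percentile bootstrap CI for the mean."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    means = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return {"mean": float(x.mean()), "ci": (float(lo), float(hi)), "n_boot": n_boot}
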