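"""Trial-level correlations, random-intercept regressions, and diagnostics.

The analysis layer mirrors a two-stage multilevel design: each eye metric
(skipping, dwelling, revisiting) is regressed on age, target-distractor
similarity, and set size (plus age x difficulty interactions), and search RT
is regressed on age and the three eye metrics together with the design
factors.  All models carry a per-participant random intercept, are estimated
by REML, and work on standardized responses and metrical predictors so the
coefficients are directly comparable; t-values are referred to the standard
normal (|t| > 1.96 significant), which is the appropriate reference with
thousands of trial-level observations.  Analyses are restricted to correct
target-absent trials, where the three distractor-rejection processes can be
observed uncontaminated by target selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

from .metrics import zscore

logger = logging.getLogger(__name__)

T_CRIT = 1.96
TOLERANCE_ACCEPTABLE = 0.70  # 1/VIF below this is flagged
TOLERANCE_CRITICAL = 0.10

#: Table-3-style variable order for the trial-level correlation matrix
CORR_VARS = ["rt", "skipping", "revisiting", "dwelling", "similarity", "set_size", "age"]

EYE_METRICS = ["skipping", "dwelling", "revisiting"]
EYE_TERMS = ["age", "similarity", "set_size", "age_x_similarity", "age_x_set_size"]
RT_TERMS = ["skipping", "dwelling", "revisiting", "age", "similarity", "set_size"]


@dataclass
class Coefficient:
    term: str
    b: float
    sd_b: float

    @property
    def t(self) -> float:
        return self.b / self.sd_b

    @property
    def significant(self) -> bool:
        return abs(self.t) > T_CRIT

    @property
    def effect_size(self) -> str:
        return effect_size_label(self.b)


@dataclass
class ModelFit:
    """A fitted random-intercept model in coefficient-table form."""

    response: str
    coefficients: dict[str, Coefficient]
    var_random_intercept: float
    var_residual: float
    marginal_r2: float
    tolerance: dict[str, float]
    n_obs: int
    n_groups: int

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "term": c.term,
                "b": c.b,
                "sd_b": c.sd_b,
                "t": c.t,
                "significant": c.significant,
                "effect_size": c.effect_size,
            }
            for c in self.coefficients.values()
        ]
        return pd.DataFrame(rows)


@dataclass
class AnalysisResults:
    """Everything the analysis stage produces for one data set."""

    eye_models: dict[str, ModelFit]
    rt_model: ModelFit
    correlations: pd.DataFrame
    n_obs: int

    def path_edges(self) -> list[dict]:
        """Two-stage regression summary as an edge list (path-diagram form)."""
        edges = []
        for resp, fit in self.eye_models.items():
            for term in EYE_TERMS:
                c = fit.coefficients[term]
                edges.append(
                    {
                        "predictor": term,
                        "outcome": resp,
                        "b": round(c.b, 4),
                        "sign": "+" if c.b > 0 else "-",
                        "significant": c.significant,
                    }
                )
        for term in RT_TERMS:
            c = self.rt_model.coefficients[term]
            edges.append(
                {
                    "predictor": term,
                    "outcome": "rt",
                    "b": round(c.b, 4),
                    "sign": "+" if c.b > 0 else "-",
                    "significant": c.significant,
                }
            )
        return edges


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def trial_correlations(trials: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations over the trial-level variables.

    Binary factors (similarity, set size) enter as their dummy codes, making
    their entries point-biserial correlations.  A constant column yields
    missing entries.  Expects correct target-absent trials.
    """
    cols = {}
    for v in CORR_VARS:
        if v == "rt":
            cols[v] = trials["rt_ms"]
        elif v == "dwelling":
            cols[v] = trials["dwelling_ms"]
        elif v == "set_size":
            cols[v] = (trials["set_size"] == trials["set_size"].max()).astype(float)
        else:
            cols[v] = trials[v]
    df = pd.DataFrame(cols).astype(float)
    if len(df.dropna(how="all")) < 3:
        raise ValueError("need at least 3 complete trials for correlations")
    return df.corr(method="pearson", min_periods=3)


# ---------------------------------------------------------------------------
# Random-intercept regression
# ---------------------------------------------------------------------------


def _check_design(X: pd.DataFrame) -> None:
    """Raise on an exactly singular fixed-effect design, naming the terms."""
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        tol = tolerance(X.drop(columns="intercept", errors="ignore"))
        bad = [t for t, v in tol.items() if v < 1e-10]
        raise ValueError(f"singular design: collinear terms {bad or list(X.columns)}")


def fit_random_intercept(
    data: pd.DataFrame,
    response: str,
    fixed_terms: list[str],
    groups: str = "participant",
) -> ModelFit:
    """REML fit of ``response ~ fixed_terms`` with a per-group intercept.

    Rows with a missing response or predictor are dropped listwise (with a
    log message).  Returns the coefficient table (b, sd(b), t), the variance
    components, the marginal R-squared, and per-predictor tolerance (1/VIF).
    """
    cols = [response] + fixed_terms + [groups]
    d = data[cols]
    n0 = len(d)
    d = d.dropna()
    if len(d) < n0:
        logger.info("%s model: %d rows dropped listwise (missing values)",
                    response, n0 - len(d))
    if d[groups].nunique() < 2:
        raise ValueError("need at least 2 groups for a random intercept")

    X = pd.DataFrame({"intercept": np.ones(len(d))}, index=d.index)
    for t in fixed_terms:
        X[t] = d[t].astype(float)
    _check_design(X)

    model = MixedLM(d[response].to_numpy(dtype=float), X.to_numpy(), groups=d[groups].to_numpy())
    res = model.fit(reml=True)
    if not res.converged:
        # gradient-based optimizers can stall near the variance boundary;
        # Powell is derivative-free and reliable there
        logger.info("%s model: gradient optimizers stalled, retrying with "
                    "Powell", response)
        res = model.fit(reml=True, method="powell", maxiter=2000)
    if not res.converged:
        raise RuntimeError(
            f"{response} model did not converge: {getattr(res, 'hist', None) or res.summary()}"
        )

    terms = ["intercept"] + fixed_terms
    coefs = {
        t: Coefficient(term=t, b=float(res.fe_params[i]), sd_b=float(res.bse[i]))
        for i, t in enumerate(terms)
    }
    var_re = float(np.asarray(res.cov_re)[0, 0])
    var_resid = float(res.scale)
    fixed_pred = X.to_numpy() @ res.fe_params
    r2 = marginal_r2(fixed_pred, var_re, var_resid)
    tol = tolerance(X.drop(columns="intercept"))
    for t, v in tol.items():
        if v <= TOLERANCE_CRITICAL:
            logger.error("%s model: tolerance of %s = %.3f at or below the "
                         "critical level %.2f", response, t, v, TOLERANCE_CRITICAL)
        elif v <= TOLERANCE_ACCEPTABLE:
            logger.warning("%s model: tolerance of %s = %.3f at or below the "
                           "acceptability bound %.2f", response, t, v,
                           TOLERANCE_ACCEPTABLE)
    return ModelFit(
        response=response,
        coefficients=coefs,
        var_random_intercept=var_re,
        var_residual=var_resid,
        marginal_r2=r2,
        tolerance=tol,
        n_obs=len(d),
        n_groups=int(d[groups].nunique()),
    )


def marginal_r2(fixed_pred: np.ndarray, var_random: float, var_residual: float) -> float:
    """Variance explained by the fixed effects alone.

    var(fixed predictions) / (var(fixed) + random-intercept variance +
    residual variance); reduces to OLS R-squared when the random variance
    is zero.
    """
    vf = float(np.var(np.asarray(fixed_pred, dtype=float)))
    denom = vf + var_random + var_residual
    return vf / denom if denom > 0 else 0.0


def tolerance(design: pd.DataFrame) -> dict[str, float]:
    """Per-predictor tolerance (1/VIF): 1 - R^2 of each column on the rest.

    Exactly collinear predictors come back with tolerance 0 (and are
    reported as a collinearity error in the log by callers).
    """
    out: dict[str, float] = {}
    arr = design.to_numpy(dtype=float)
    n, p = arr.shape
    if p == 1:
        return {design.columns[0]: 1.0}
    for j, name in enumerate(design.columns):
        y = arr[:, j]
        X = np.column_stack([np.ones(n), np.delete(arr, j, axis=1)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sst = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 1.0
        out[name] = float(max(0.0, 1.0 - r2))
    return out


# ---------------------------------------------------------------------------
# Effect sizes and power
# ---------------------------------------------------------------------------


def effect_size_label(b: float) -> str:
    """Bin a standardized coefficient: very small / small / medium / large.

    Cut points: |b| < 0.10 very small, 0.10-0.29 small, 0.30-0.49 medium,
    above 0.50 large (0.50 itself still counts as medium).
    """
    a = abs(float(b))
    if not np.isfinite(a):
        raise ValueError("coefficient must be finite")
    if a < 0.10:
        return "very small"
    if a < 0.30:
        return "small"
    if a <= 0.50:
        return "medium"
    return "large"


def correlation_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Two-sided power of the test of a Pearson correlation, via Fisher's z.

    Under rho = r the statistic atanh(r_hat)*sqrt(n-3) is approximately
    Normal(atanh(r)*sqrt(n-3), 1); power is the probability of exceeding the
    two-sided alpha critical value.  At r = 0 this returns alpha exactly.
    """
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if n < 4:
        raise ValueError("n must be at least 4")
    za = sps.norm.ppf(1 - alpha / 2)
    delta = np.arctanh(r) * np.sqrt(n - 3)
    return float(sps.norm.sf(za - delta) + sps.norm.cdf(-za - delta))


# ---------------------------------------------------------------------------
# The full analysis
# ---------------------------------------------------------------------------


def prepare_analysis_table(trials: pd.DataFrame, require_rt: bool = True) -> pd.DataFrame:
    """Select correct target-absent trials and standardize for modeling.

    Metrical variables (RT, skipping, dwelling, revisiting) and age are
    z-transformed pooled across trials; the design factors keep their dummy
    codes (dissimilar = 0 / similar = 1; set size 5 = 0 / 10 = 1) and the
    interactions are products of standardized age with the dummies.
    """
    d = trials[(~trials["target_present"].astype(bool)) & trials["correct"].astype(bool)]
    if require_rt:
        d = d[d["rt_ms"].notna()]
    d = d.copy()
    d["set_size_d"] = (d["set_size"] == d["set_size"].max()).astype(float)
    out = pd.DataFrame(index=d.index)
    out["participant"] = d["participant"]
    out["similarity"] = d["similarity"].astype(float)
    out["set_size"] = d["set_size_d"]
    for raw, name in [("rt_ms", "rt"), ("skipping", "skipping"),
                      ("dwelling_ms", "dwelling"), ("revisiting", "revisiting"),
                      ("age", "age")]:
        try:
            out[name] = zscore(d[raw])
        except ValueError as e:
            raise ValueError(f"cannot standardize {name}: {e}") from e
    out["age_x_similarity"] = out["age"] * out["similarity"]
    out["age_x_set_size"] = out["age"] * out["set_size"]
    return out


def run_paper_models(trials: pd.DataFrame) -> AnalysisResults:
    """Fit the full two-stage analysis on filtered trial statistics.

    Stage 1: skipping, dwelling, and revisiting each regressed on age,
    similarity, set size, and the two age x difficulty interactions.
    Stage 2: RT regressed on the three eye metrics, age, similarity, and set
    size.  All models: random intercept per participant, correct target-absent
    trials only.  Also returns the trial-level correlation matrix.
    """
    analysis = prepare_analysis_table(trials)
    sel = trials[(~trials["target_present"].astype(bool))
                 & trials["correct"].astype(bool) & trials["rt_ms"].notna()]
    corr = trial_correlations(sel)

    eye_models = {
        m: fit_random_intercept(analysis, m, EYE_TERMS) for m in EYE_METRICS
    }
    rt_model = fit_random_intercept(analysis, "rt", RT_TERMS)
    return AnalysisResults(
        eye_models=eye_models,
        rt_model=rt_model,
        correlations=corr,
        n_obs=len(analysis),
    )
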