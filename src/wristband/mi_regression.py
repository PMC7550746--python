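"""Chained-equation imputation, OLS fits, and Rubin's-rules pooling.

Missing covariates are filled by multivariate imputation by chained
equations (MICE): each incomplete variable is visited in turn and imputed
from a conditional model given all other variables — predictive mean
matching for continuous variables, a Bayesian logistic draw for binary
variables, and a multinomial draw for multi-category variables.  The sweep
repeats ``n_iter`` times per dataset and the whole procedure is run ``m``
times (default 25) to produce ``m`` completed datasets.

Each analysis model is an ordinary least-squares regression fit once per
completed dataset; estimates are pooled with Rubin's rules,

    qbar = mean(q_j),  W = mean(U_j),  B = var(q_j),
    T = W + (1 + 1/m) B,

with Barnard-Rubin small-sample degrees of freedom for the t-based 95%
confidence intervals.  With no missing data every imputed dataset equals
the input and the pooled fit reduces exactly to the complete-data OLS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationSpec",
    "PooledFit",
    "chained_impute",
    "design_matrix",
    "fit_linear",
    "pool_rubin",
    "run_model_suite",
    "TABLE_COVARIATES",
    "REFERENCE_LEVELS",
]

#: Adjustment covariates shared by every multivariable model.
TABLE_COVARIATES = [
    "age_years",
    "bmi",
    "education",
    "marital",
    "race_ethnicity",
    "parity",
    "smoke_exposure",
    "gestational_age_start",
    "season",
]

#: Reference level per categorical term (the omitted dummy).
REFERENCE_LEVELS = {
    "education": "less than college graduate",
    "marital": "married",
    "race_ethnicity": "White non-Hispanic",
    "parity": "0",
    "smoke_exposure": "none",
    "season": "fall",
    "nail_polish_use": "no",
    "gardening": "no",
}


@dataclass
class ImputationSpec:
    m: int = 25
    n_iter: int = 10
    pmm_donors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least 2 imputations")
        if self.n_iter < 1:
            raise ValueError("need at least 1 chained-equation sweep")


@dataclass
class PooledFit:
    name: str
    m: int
    table: pd.DataFrame  # term, beta, W, B, T, df, ci_low, ci_high

    @property
    def terms(self) -> list[str]:
        return list(self.table["term"])

    def beta(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "beta"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.table.set_index("term").loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


# ---------------------------------------------------------------------------
# chained imputation
# ---------------------------------------------------------------------------

def _predictor_matrix(df: pd.DataFrame, exclude: str) -> np.ndarray:
    """Dummy-coded predictor matrix (with intercept) from all other columns."""
    cols = [c for c in df.columns if c != exclude]
    X = pd.get_dummies(df[cols], drop_first=True, dtype=float)
    return np.column_stack([np.ones(len(df)), X.to_numpy(dtype=float)])


def _pmm_impute(y: pd.Series, X: np.ndarray, miss: np.ndarray,
                rng: np.random.Generator, k: int) -> np.ndarray:
    """Predictive mean matching with a Bayesian linear-regression draw."""
    obs = ~miss
    Xo, yo = X[obs], y[obs].to_numpy(dtype=float)
    n, p = Xo.shape
    beta_hat, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta_hat
    nu = max(n - p, 1)
    sigma2 = resid @ resid / stats.chi2.rvs(nu, random_state=rng)
    XtX_inv = np.linalg.pinv(Xo.T @ Xo)
    cov = sigma2 * XtX_inv
    # symmetrize before factorizing; pinv can leave tiny asymmetries
    L = np.linalg.cholesky((cov + cov.T) / 2 + 1e-12 * np.eye(p))
    beta_star = beta_hat + L @ rng.standard_normal(p)
    pred_obs = Xo @ beta_hat
    pred_mis = X[miss] @ beta_star
    out = np.empty(miss.sum())
    kk = min(k, n)
    for i, pm in enumerate(pred_mis):
        donors = np.argsort(np.abs(pred_obs - pm))[:kk]
        out[i] = yo[donors[rng.integers(kk)]]
    return out


def _categorical_impute(y: pd.Series, X: np.ndarray, miss: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw missing categories from a (multi)nomial logistic model.

    Falls back to the observed marginal frequencies when the likelihood fit
    fails (e.g. perfect separation on a small resample).
    """
    obs = ~miss
    yo = y[obs]
    levels = sorted(yo.unique())
    if len(levels) == 1:
        return np.repeat(levels[0], miss.sum())
    codes = yo.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    Xo, Xm = X[obs], X[miss]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if len(levels) == 2:
                fit = sm.Logit(codes, Xo).fit(disp=0, maxiter=100)
                params = np.asarray(fit.params)
                cov = np.asarray(fit.cov_params())
                L = np.linalg.cholesky((cov + cov.T) / 2 + 1e-10 * np.eye(len(params)))
                draw = params + L @ rng.standard_normal(len(params))
                p1 = 1.0 / (1.0 + np.exp(-(Xm @ draw)))
                picks = (rng.random(len(p1)) < p1).astype(int)
            else:
                fit = sm.MNLogit(codes, Xo).fit(disp=0, maxiter=100)
                params = np.asarray(fit.params)  # (p, K-1)
                flat = params.ravel(order="F")
                cov = np.asarray(fit.cov_params())
                L = np.linalg.cholesky((cov + cov.T) / 2 + 1e-10 * np.eye(len(flat)))
                draw = (flat + L @ rng.standard_normal(len(flat))).reshape(
                    params.shape, order="F"
                )
                eta = np.column_stack([np.zeros(len(Xm)), Xm @ draw])
                eta -= eta.max(axis=1, keepdims=True)
                prob = np.exp(eta)
                prob /= prob.sum(axis=1, keepdims=True)
                picks = np.array([rng.choice(len(levels), p=pr) for pr in prob])
            if not np.all(np.isfinite(picks)):
                raise np.linalg.LinAlgError
    except Exception:
        freq = yo.value_counts(normalize=True).reindex(levels).to_numpy()
        picks = rng.choice(len(levels), size=miss.sum(), p=freq)
    return np.asarray([levels[i] for i in np.asarray(picks).ravel()])


def chained_impute(data: pd.DataFrame, spec: ImputationSpec) -> list[pd.DataFrame]:
    """Produce ``spec.m`` completed copies of ``data``.

    Numeric columns are imputed by predictive mean matching, object/categorical
    columns by (multi)nomial logistic draws.  Observed cells are never
    altered.  A variable missing in more than 95% of rows is refused.
    """
    data = data.copy()
    miss_mask = data.isna()
    frac = miss_mask.mean()
    too_missing = frac[frac > 0.95]
    if len(too_missing):
        raise ValueError(f"variable(s) with >95% missingness: {list(too_missing.index)}")
    if frac.sum() == 0:
        return [data.copy() for _ in range(spec.m)]
    incomplete = [c for c in data.columns if miss_mask[c].any()]
    numeric = {c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])}

    completed = []
    root = np.random.default_rng(spec.seed)
    child_seeds = root.integers(0, 2**31 - 1, size=spec.m)
    for j in range(spec.m):
        rng = np.random.default_rng(child_seeds[j])
        df = data.copy()
        # initial fill: random draws from the observed marginal
        for c in incomplete:
            obs_vals = data[c].dropna().to_numpy()
            df.loc[miss_mask[c], c] = rng.choice(obs_vals, size=miss_mask[c].sum())
        if set(numeric) & set(incomplete):
            for c in set(numeric) & set(incomplete):
                df[c] = pd.to_numeric(df[c])
        for _ in range(spec.n_iter):
            for c in incomplete:
                miss = miss_mask[c].to_numpy()
                X = _predictor_matrix(df, exclude=c)
                if c in numeric:
                    df.loc[miss, c] = _pmm_impute(data[c], X, miss, rng, spec.pmm_donors)
                else:
                    df.loc[miss, c] = _categorical_impute(data[c], X, miss, rng)
        completed.append(df)
    return completed


# ---------------------------------------------------------------------------
# design + OLS + pooling
# ---------------------------------------------------------------------------

def design_matrix(df: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Intercept + dummy-expanded design with fixed reference levels."""
    cols = {"Intercept": np.ones(len(df))}
    for t in terms:
        s = df[t]
        if pd.api.types.is_numeric_dtype(s):
            cols[t] = s.to_numpy(dtype=float)
        else:
            observed = sorted(map(str, pd.unique(s.dropna())))
            ref = REFERENCE_LEVELS.get(t, observed[0] if observed else None)
            levels = [lv for lv in observed if lv != ref]
            for lv in sorted(map(str, levels)):
                cols[f"{t}[{lv}]"] = (s.astype(str) == lv).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def fit_linear(outcome: pd.Series | np.ndarray, design: pd.DataFrame):
    """OLS fit; returns the statsmodels results object.

    Rank-deficient designs are rejected with the aliased columns named.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n = {n} <= p = {p}")
    if np.linalg.matrix_rank(X) < p:
        aliased = []
        rank = 0
        for j in range(p):
            r = np.linalg.matrix_rank(X[:, : j + 1])
            if r == rank:
                aliased.append(design.columns[j])
            rank = r
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    y = np.asarray(outcome, dtype=float)
    model = sm.OLS(y, X)
    fit = model.fit()
    fit.term_names = list(design.columns)
    return fit


def pool_rubin(fits: list) -> PooledFit:
    """Combine per-imputation OLS fits with Rubin's rules."""
    if not fits:
        raise ValueError("no fits to pool")
    terms = getattr(fits[0], "term_names", None) or [f"x{i}" for i in range(len(fits[0].params))]
    for f in fits:
        if (getattr(f, "term_names", terms) or terms) != terms:
            raise ValueError("mismatched terms across imputations")
    m = len(fits)
    Q = np.array([np.asarray(f.params) for f in fits])
    U = np.array([np.diag(np.asarray(f.cov_params())) for f in fits])
    qbar = Q.mean(axis=0)
    W = U.mean(axis=0)
    # center on the first fit so identical fits give exactly B = 0
    B = (Q - Q[0]).var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    T = W + (1 + 1 / m) * B
    nu_com = float(fits[0].df_resid)
    dfs, ci_lo, ci_hi = [], [], []
    for j in range(len(terms)):
        if B[j] <= 0 or T[j] <= 0:
            df = nu_com
        else:
            lam = (1 + 1 / m) * B[j] / T[j]
            df_old = (m - 1) / lam**2
            df_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        dfs.append(df)
        half = stats.t.ppf(0.975, df) * np.sqrt(T[j])
        ci_lo.append(qbar[j] - half)
        ci_hi.append(qbar[j] + half)
    table = pd.DataFrame(
        {
            "term": terms,
            "beta": qbar,
            "W": W,
            "B": B,
            "T": T,
            "df": dfs,
            "ci_low": ci_lo,
            "ci_high": ci_hi,
        }
    )
    return PooledFit(name="", m=m, table=table)


# ---------------------------------------------------------------------------
# the model suite
# ---------------------------------------------------------------------------

#: a-priori hypotheses: exposure term -> list of (outcome kind, outcome id)
APRIORI_MODELS = [
    ("nail_polish_use", [("count", "personal care products"),
                         ("chemical", "Triphenyl phosphate"),
                         ("chemical", "Di-n-butyl phthalate"),
                         ("chemical", "Diisobutyl phthalate"),
                         ("chemical", "Butyl benzyl phthalate"),
                         ("chemical", "Di-n-nonyl phthalate"),
                         ("chemical", "Diethyl phthalate")]),
    ("handwashing_per_day", [("count", "total")]),
    ("gardening", [("count", "pesticides"),
                   ("chemical", "N,N-Diethyl-m-toluamide"),
                   ("chemical", "Benzyl benzoate"),
                   ("chemical", "Permethrin"),
                   ("chemical", "Di-n-butyl phthalate"),
                   ("chemical", "Diethyl phthalate")]),
    ("parity", [("chemical", "Triphenyl phosphate")]),
    ("season", [("chemical", "Benzophenone"),
                ("count", "pesticides")]),
]


def run_model_suite(std, counts: pd.DataFrame, cov, spec: ImputationSpec,
                    extra_sample_cols: pd.DataFrame | None = None) -> dict[str, PooledFit]:
    """Fit the predictor model, the a-priori hypotheses, and per-chemical
    season models, each multiply imputed and Rubin-pooled.

    ``std`` is the standardized (detection-filtered) matrix; ``counts`` the
    per-wristband detect counts; ``cov`` the covariate table.  Season and
    gestational age at start are taken from the sample metadata when not in
    the covariate table.  A hypothesis whose target chemical did not survive
    the detection screen is skipped with a warning — such relations are
    untestable at the achieved detection frequencies.
    """
    cov_df = cov.data if hasattr(cov, "data") else cov.copy()
    samples = std.samples.set_index("participant_id")
    frame = cov_df.copy()
    for col in ("season", "gestational_age_start"):
        if col not in frame.columns:
            frame[col] = samples.loc[frame.index, col]
    analysis_cols = sorted(set(TABLE_COVARIATES) | {"nail_polish_use", "handwashing_per_day", "gardening"})
    frame = frame[analysis_cols]

    # align outcomes to participants
    values = std.values.copy()
    values.index = std.samples["participant_id"]
    counts = counts.copy()
    counts.index = std.samples["participant_id"]
    frame = frame.loc[values.index]

    # single imputation pass over covariates + the count outcome (the
    # chained models therefore see the main analysis outcome as a predictor)
    imp_frame = frame.copy()
    imp_frame["__total__"] = counts["total"].to_numpy(dtype=float)
    completed = chained_impute(imp_frame, spec)

    def pooled(outcome: np.ndarray, terms: list[str], name: str) -> PooledFit:
        fits = []
        for df in completed:
            X = design_matrix(df, terms)
            fits.append(fit_linear(outcome, X))
        pf = pool_rubin(fits)
        pf.name = name
        return pf

    results: dict[str, PooledFit] = {}
    results["total_detects"] = pooled(
        counts["total"].to_numpy(dtype=float), TABLE_COVARIATES, "total_detects"
    )

    present = set(std.chemical_ids)
    for exposure, outcomes in APRIORI_MODELS:
        terms = TABLE_COVARIATES if exposure in TABLE_COVARIATES else TABLE_COVARIATES + [exposure]
        for kind, ident in outcomes:
            name = f"{exposure}~{ident}"
            if kind == "chemical":
                if ident not in present:
                    logger.warning(
                        "skipping %s: %r not detected frequently enough to model", name, ident
                    )
                    continue
                y = values[ident].to_numpy(dtype=float)
            else:
                y = counts[ident].to_numpy(dtype=float)
            results[name] = pooled(y, terms, name)

    for chem in std.chemical_ids:
        name = f"season~{chem}"
        results[name] = pooled(values[chem].to_numpy(dtype=float), TABLE_COVARIATES, name)
    return results
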