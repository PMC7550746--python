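"""Correlation structure and temporal reproducibility of wristband chemicals.

Reproducibility between the two pregnancy timepoints is quantified by the
intraclass correlation coefficient (ICC) of a random-intercept model

    y_it = mu + beta * week_t + u_i + e_it,
    u_i ~ N(0, sigma2_between),  e_it ~ N(0, sigma2_within),

    ICC = sigma2_between / (sigma2_between + sigma2_within).

With exactly two occasions per participant the REML variance components
have a closed form: sigma2_within = Var(d_i)/2 from the within-pair
differences d_i (the week fixed effect is absorbed by centering the
differences) and sigma2_between = Var(m_i) - sigma2_within/2 from the
participant means m_i, truncated at zero.  Confidence intervals come from
a participant-level nonparametric bootstrap (both occasions resampled
together, preserving within-person dependence), with percentile bounds
clamped to [0, 1].

ICCs <= 0.4 designate poor, 0.4-0.75 fair to good, and >= 0.75 excellent
reproducibility (the Rosner cutpoints).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import StandardizedMatrix

__all__ = [
    "ICCEstimate",
    "spearman_matrix",
    "paired_values",
    "estimate_icc",
    "estimate_icc_matrix",
    "classify_icc",
    "classify_and_summarize",
]

CLASS_POOR = "poor"
CLASS_FAIR = "fair to good"
CLASS_EXCELLENT = "excellent"


@dataclass
class ICCEstimate:
    chemical_id: str
    sigma2_between: float
    sigma2_within: float
    icc: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_pairs: int
    reliability_class: str
    degenerate: bool = False


def spearman_matrix(std: StandardizedMatrix) -> tuple[pd.DataFrame, dict]:
    """Spearman correlations among chemicals, plus an off-diagonal summary.

    Ranks use midranks for ties, so blocks of shared non-detect zeros tie
    as expected.  A chemical whose values are all identical has undefined
    rank correlation; its row/column is reported as NaN with a warning.
    """
    v = std.values
    if v.shape[1] < 2 or v.shape[0] < 3:
        raise ValueError("need at least 2 chemicals and 3 samples")
    constant = [c for c in v.columns if v[c].nunique() <= 1]
    if constant:
        warnings.warn(f"all-tied chemical(s), correlation undefined: {constant}", stacklevel=2)
    ranks = np.apply_along_axis(stats.rankdata, 0, v.to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    rho = pd.DataFrame(corr, index=v.columns, columns=v.columns)
    for c in constant:
        rho.loc[c, :] = np.nan
        rho.loc[:, c] = np.nan
    np.fill_diagonal(rho.values, 1.0)
    off = rho.to_numpy()[np.triu_indices(len(rho), k=1)]
    off = off[~np.isnan(off)]
    summary = {
        "median": float(np.median(off)),
        "q1": float(np.quantile(off, 0.25)),
        "q3": float(np.quantile(off, 0.75)),
        "min": float(off.min()),
        "max": float(off.max()),
    }
    return rho, summary


def paired_values(std: StandardizedMatrix, chemical: str,
                  timepoints: tuple[str, str] = ("week12", "week24")) -> np.ndarray:
    """Extract an (n, 2) array of per-participant values at both timepoints.

    Participants missing either occasion are excluded.
    """
    t1, t2 = timepoints
    s = std.samples
    v = std.values[chemical]
    a = v[s["timepoint"] == t1]
    b = v[s["timepoint"] == t2]
    a.index = s.loc[a.index, "participant_id"]
    b.index = s.loc[b.index, "participant_id"]
    common = a.index.intersection(b.index)
    return np.column_stack([a.loc[common].to_numpy(), b.loc[common].to_numpy()])


def _closed_form(pairs: np.ndarray) -> tuple[float, float, float]:
    """(sigma2_between, sigma2_within, icc) for balanced two-occasion data."""
    d = pairs[:, 0] - pairs[:, 1]
    m = pairs.mean(axis=1)
    s2w = float(np.var(d, ddof=1) / 2)
    s2b = max(float(np.var(m, ddof=1) - s2w / 2), 0.0)
    tot = s2b + s2w
    return s2b, s2w, (s2b / tot if tot > 0 else 0.0)


def estimate_icc(
    pairs: np.ndarray,
    chemical_id: str = "",
    n_boot: int = 1000,
    seed: int = 0,
) -> ICCEstimate:
    """ICC point estimate with a participant-bootstrap percentile 95% CI.

    ``pairs`` is an (n, 2) array of the chemical's (standardized) values at
    the first and second occasion.  Degenerate inputs (all participants
    identical) yield ICC 0 with both variance components 0, flagged; a
    degenerate bootstrap resample contributes ICC 0.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    n = pairs.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants with both occasions")
    degenerate = bool(np.allclose(pairs, pairs[0]))
    if degenerate:
        s2b = s2w = icc = 0.0
    else:
        s2b, s2w, icc = _closed_form(pairs)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        sub = pairs[idx[b]]
        if np.allclose(sub, sub[0]):
            boot[b] = 0.0
        else:
            boot[b] = _closed_form(sub)[2]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ICCEstimate(
        chemical_id=chemical_id,
        sigma2_between=s2b,
        sigma2_within=s2w,
        icc=icc,
        ci_low=float(np.clip(lo, 0, 1)),
        ci_high=float(np.clip(hi, 0, 1)),
        n_boot=n_boot,
        n_pairs=n,
        reliability_class=classify_icc(icc),
        degenerate=degenerate,
    )


def estimate_icc_matrix(
    std: StandardizedMatrix, n_boot: int = 1000, seed: int = 0
) -> list[ICCEstimate]:
    """ICC per chemical from a standardized two-timepoint matrix."""
    out = []
    for j, chem in enumerate(std.chemical_ids):
        pairs = paired_values(std, chem)
        out.append(estimate_icc(pairs, chem, n_boot=n_boot, seed=seed + j))
    return out


def classify_icc(icc: float) -> str:
    """Rosner reproducibility class: <=0.4 poor, (0.4, 0.75) fair to good, >=0.75 excellent."""
    if icc >= 0.75:
        return CLASS_EXCELLENT
    if icc > 0.4:
        return CLASS_FAIR
    return CLASS_POOR


def classify_and_summarize(iccs: list[float] | list[ICCEstimate]) -> tuple[pd.DataFrame, dict]:
    """Classify each ICC and summarize the cohort's reproducibility.

    Returns a per-chemical table and a summary dict with the median ICC,
    the range, and the percentage (rounded to the nearest integer) in each
    reliability class.
    """
    if not len(iccs):
        raise ValueError("empty ICC list")
    if isinstance(iccs[0], ICCEstimate):
        table = pd.DataFrame(
            {
                "chemical_id": [e.chemical_id for e in iccs],
                "icc": [e.icc for e in iccs],
                "ci_low": [e.ci_low for e in iccs],
                "ci_high": [e.ci_high for e in iccs],
            }
        )
    else:
        table = pd.DataFrame({"chemical_id": "", "icc": np.asarray(iccs, dtype=float)})
    table["reliability_class"] = [classify_icc(x) for x in table["icc"]]
    n = len(table)
    summary = {
        "median_icc": float(table["icc"].median()),
        "min_icc": float(table["icc"].min()),
        "max_icc": float(table["icc"].max()),
    }
    for cls in (CLASS_POOR, CLASS_FAIR, CLASS_EXCELLENT):
        summary[f"pct_{cls.replace(' ', '_')}"] = int(
            round(100 * (table["reliability_class"] == cls).sum() / n)
        )
    return table, summary
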