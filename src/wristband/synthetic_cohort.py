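"""Synthetic wristband cohorts with known ground truth.

Concentrations follow a left-censored base-10 lognormal model, the standard
working assumption for passive-sampler data whose medians and IQRs are
strongly right-skewed.  For participant i and chemical c the log10
concentration is

    log10 x_ic = mu_c + profile_shift(p_i, c) + batch_shift(b_i, c)
                 + sum_k beta_k z_ik + sigma_c eps_ic

and x_ic is reported as 0 (non-detect) whenever it falls below the
chemical's quantitation limit.  The expected detection fraction is
therefore 1 - Phi((log10 loq_c - mu_c) / sigma_c), so per-chemical
detection frequencies and medians can be dialled in directly from targets.

Latent multipollutant profiles are planted as additive log-scale shifts on
chemical subsets; covariate effects (e.g. nail-polish use raising a
plasticizer, season shifting a UV-blocker) are additive on the same scale.
The repeated-measures design draws a participant random intercept u_i and
occasion noise e_it with variances chosen per chemical, so the true ICC
sigma2_b / (sigma2_b + sigma2_w) is known exactly.

Every draw flows from one ``numpy`` generator seeded from the config, so a
fixed config + seed reproduces byte-identical CSV output.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exposure_data import (
    ChemicalRecord,
    CovariateTable,
    ExposureMatrix,
    season_of,
)
from . import reference

__all__ = [
    "CovariateEffect",
    "SimulationConfig",
    "TruthLedger",
    "default_config",
    "simulate_cohort",
    "simulate_repeated",
]


@dataclass(frozen=True)
class CovariateEffect:
    """An additive log10-scale effect of a covariate level on one chemical.

    ``covariate`` is either a binary/categorical spec ``"column=level"``
    (indicator effect) or a bare continuous column name (per-unit slope).
    ``chemical`` may be ``"*"`` to shift every chemical, which perturbs the
    number of chemicals detected rather than any single concentration.
    """

    covariate: str
    chemical: str
    beta: float


@dataclass
class SimulationConfig:
    n_participants: int = 255
    n_chemicals: int = 40
    n_batches: int = 3
    #: (weight, {chemical_id: log10 shift}) per latent profile
    profile_spec: list[tuple[float, dict[str, float]]] = field(default_factory=list)
    #: per-chemical baseline mean of log10 concentration (log10 ng/g)
    log_mu: dict[str, float] = field(default_factory=dict)
    #: per-chemical SD of log10 concentration
    log_sigma: dict[str, float] = field(default_factory=dict)
    #: per-chemical quantitation limit (ng/g); values below are reported 0
    loq: dict[str, float] = field(default_factory=dict)
    batch_shift_sd: float = 0.15
    #: per-chemical (sigma2_between, sigma2_within) on the log10 scale
    icc_targets: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_repeated: int = 20
    #: fixed log10 shift of the second occasion in the repeated design
    week_effect: float = 0.2
    covariate_effects: list[CovariateEffect] = field(default_factory=list)
    #: MCAR missingness fraction per covariate column
    missingness: dict[str, float] = field(
        default_factory=lambda: {"education": 0.28, "marital": 0.28, "smoke_exposure": 0.30}
    )
    chemical_records: list[ChemicalRecord] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.n_chemicals <= 0:
            raise ValueError("n_participants and n_chemicals must be positive")
        if self.n_repeated > self.n_participants:
            raise ValueError("n_repeated cannot exceed n_participants")
        if self.profile_spec:
            total = sum(w for w, _ in self.profile_spec)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"profile weights must sum to 1, got {total}")
        for c, (s2b, s2w) in self.icc_targets.items():
            if s2b < 0 or s2w < 0:
                raise ValueError(f"negative variance component for {c!r}")

    @property
    def chemical_ids(self) -> list[str]:
        return list(self.log_mu)


@dataclass
class TruthLedger:
    """Ground truth recorded alongside a simulated cohort."""

    seed: int
    profile_labels: dict[str, int] = field(default_factory=dict)
    true_icc: dict[str, float] = field(default_factory=dict)
    true_effects: list[dict] = field(default_factory=list)
    expected_detection: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


# Marginal covariate distributions chosen to mirror a well-educated,
# predominantly married and White non-Hispanic New England prenatal-care
# population; season-of-wear frequencies favour fall.
_EDU_LEVELS = ("less than college graduate", "college graduate", "any post-graduate")
_EDU_P = (0.25, 0.44, 0.31)
_SEASON_P = {"fall": 0.37, "spring": 0.25, "summer": 0.18, "winter": 0.20}
_SEASON_MONTHS = {"winter": (12, 1, 2), "spring": (3, 4, 5), "summer": (6, 7, 8), "fall": (9, 10, 11)}


def default_config(seed: int = 0) -> SimulationConfig:
    """Default cohort: 255 participants, 40 chemicals, 3 batches, 20 repeats.

    The 17 panel chemicals keep their reported detection frequencies,
    medians and ICCs; 23 filler chemicals are sporadically detected
    (1-35%), mirroring the long tail of a broad screen in which most
    assayed chemicals appear in few wristbands.
    """
    panel = reference.reference_panel()
    sigma = 0.6
    log_mu, log_sigma, loq, icc_targets = {}, {}, {}, {}
    records = list(reference.reference_chemicals())
    detection_target = {}
    for name, row in panel.iterrows():
        p = row["pct_detected_12wk"] / 100.0
        mu = float(np.log10(max(row["median_12wk"], 1.0)))
        log_mu[name] = mu
        log_sigma[name] = sigma
        detection_target[name] = p
        icc = float(row["icc"])
        icc_targets[name] = (icc * sigma**2, (1 - icc) * sigma**2)
    filler_p = np.linspace(0.55, 0.02, 23)
    filler_cats = [
        "PAHs", "flame retardants", "consumer products", "chemicals in commerce",
        "pesticides", "personal care products", "pharmacological",
    ]
    for j, p in enumerate(filler_p):
        name = f"filler_{j + 1:02d}"
        log_mu[name] = 1.5 + 0.05 * j
        log_sigma[name] = sigma
        detection_target[name] = float(p)
        icc_targets[name] = (0.1 * sigma**2, 0.9 * sigma**2)
        records.append(
            ChemicalRecord(
                chemical_id=name,
                name=name,
                casn=f"{9000 + j}-00-0",
                categories=frozenset({filler_cats[j % len(filler_cats)]}),
            )
        )
    profile_spec = [
        # dominant low-exposure profile
        (0.58, {c: -0.20 for c in panel.index}),
        # elevated polycyclic musk + benzoate
        (0.13, {"Galaxolide": 1.0, "Benzyl benzoate": 1.0}),
        # elevated single plasticizer
        (0.08, {"Butyl benzyl phthalate": 1.2}),
        # elevated phenolic antioxidant
        (0.06, {"2,4-Di-tert-butylphenol": 1.2}),
        # moderate-everything remainder
        (0.15, {}),
    ]
    effects = [
        CovariateEffect("nail_polish_use=yes", "Diethyl phthalate", 0.25),
        CovariateEffect("season=summer", "Benzophenone", 0.30),
        CovariateEffect("season=winter", "Ethylene brassylate", 0.25),
        CovariateEffect("education=any post-graduate", "*", -0.05),
        CovariateEffect("season=summer", "*", -0.06),
        CovariateEffect("season=winter", "*", -0.05),
    ]
    # quantitation limits placed so the *marginal* detection fraction hits
    # its target under the full mixture: account for the mean shift and
    # extra variance contributed by profiles, batch offsets and covariates
    prevalence = {
        "nail_polish_use=yes": 0.5,
        "season=summer": _SEASON_P["summer"],
        "season=winter": _SEASON_P["winter"],
        "education=any post-graduate": _EDU_P[2],
    }
    batch_sd = 0.15
    for name in log_mu:
        shifts = np.array([spec.get(name, 0.0) for _, spec in profile_spec])
        weights = np.array([w for w, _ in profile_spec])
        mean_shift = float(weights @ shifts)
        var_shift = float(weights @ (shifts - mean_shift) ** 2)
        for eff in effects:
            if eff.chemical in (name, "*"):
                prev = prevalence[eff.covariate]
                mean_shift += eff.beta * prev
                var_shift += eff.beta**2 * prev * (1 - prev)
        sigma_eff = float(np.sqrt(sigma**2 + var_shift + batch_sd**2))
        loq[name] = float(
            10 ** (log_mu[name] + mean_shift + sigma_eff * stats.norm.ppf(1 - detection_target[name]))
        )
    return SimulationConfig(
        profile_spec=profile_spec,
        log_mu=log_mu,
        log_sigma=log_sigma,
        loq=loq,
        icc_targets=icc_targets,
        covariate_effects=effects,
        chemical_records=records,
        seed=seed,
    )


def _draw_covariates(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_participants
    pid = [f"P{i + 1:04d}" for i in range(n)]
    seasons = rng.choice(list(_SEASON_P), size=n, p=list(_SEASON_P.values()))
    df = pd.DataFrame(
        {
            "age_years": np.round(rng.normal(31, 4.5, n).clip(18, 45), 1),
            "bmi": np.round(np.exp(rng.normal(np.log(25.5), 0.18, n)).clip(16, 55), 1),
            "education": rng.choice(_EDU_LEVELS, size=n, p=_EDU_P),
            "marital": rng.choice(["married", "unmarried"], size=n, p=[0.82, 0.18]),
            "race_ethnicity": rng.choice(["White non-Hispanic", "other"], size=n, p=[0.78, 0.22]),
            "parity": rng.choice(["0", ">=1"], size=n, p=[0.47, 0.53]),
            "smoke_exposure": rng.choice(["none", "first- or second-hand"], size=n, p=[0.86, 0.14]),
            "nail_polish_use": rng.choice(["yes", "no"], size=n, p=[0.5, 0.5]),
            "handwashing_per_day": np.round(rng.gamma(9.0, 1.1, n)).clip(0, 40),
            "gardening": rng.choice(["yes", "no"], size=n, p=[0.25, 0.75]),
            "season": seasons,
            "gestational_age_start": np.round(rng.normal(13.2, 1.6, n).clip(9, 20), 1),
        },
        index=pd.Index(pid, name="participant_id"),
    )
    return df


def _random_date_in_season(season: str, rng: np.random.Generator) -> _dt.date:
    month = int(rng.choice(_SEASON_MONTHS[season]))
    year = 2017 if month >= 3 else 2018  # keep December-winter with Jan/Feb of next year
    day = int(rng.integers(1, 29))
    return _dt.date(year, month, day)


def _effect_design(effects, cov: pd.DataFrame):
    """Resolve each effect to (per-participant multiplier vector, chemical, beta)."""
    resolved = []
    for eff in effects:
        if "=" in eff.covariate:
            col, level = eff.covariate.split("=", 1)
            z = (cov[col] == level).to_numpy(float)
        else:
            z = cov[eff.covariate].to_numpy(float)
        resolved.append((z, eff.chemical, eff.beta))
    return resolved


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExposureMatrix, CovariateTable, list[ChemicalRecord], TruthLedger]:
    """Simulate the single-timepoint (~12 week) cohort.

    Returns the exposure matrix, the covariate table (with planted MCAR
    missingness), the chemical metadata, and the truth ledger.
    """
    rng = np.random.default_rng(config.seed)
    chems = config.chemical_ids
    if len(chems) != config.n_chemicals:
        # configs built by hand may list fewer chemicals than n_chemicals
        config = dataclasses.replace(config, n_chemicals=len(chems))
    cov_full = _draw_covariates(config, rng)
    n, m = config.n_participants, len(chems)

    # latent profile memberships
    if config.profile_spec:
        weights = np.array([w for w, _ in config.profile_spec])
        labels = rng.choice(len(weights), size=n, p=weights)
    else:
        labels = np.zeros(n, dtype=int)

    mu = np.array([config.log_mu[c] for c in chems])
    sig = np.array([config.log_sigma[c] for c in chems])
    loq = np.array([config.loq[c] for c in chems])
    chem_ix = {c: j for j, c in enumerate(chems)}

    logx = mu[None, :] + rng.normal(0.0, 1.0, (n, m)) * sig[None, :]
    for k, (_, shifts) in enumerate(config.profile_spec):
        rows = labels == k
        for c, delta in shifts.items():
            logx[rows, chem_ix[c]] += delta

    batches = np.array([f"B{1 + i % config.n_batches}" for i in range(n)])
    rng.shuffle(batches)
    batch_eff = rng.normal(0.0, config.batch_shift_sd, (config.n_batches, m))
    batch_index = np.array([int(b[1:]) - 1 for b in batches])
    logx += batch_eff[batch_index]

    true_effects = []
    for z, chem, beta in _effect_design(config.covariate_effects, cov_full):
        if chem == "*":
            logx += beta * z[:, None]
        else:
            logx[:, chem_ix[chem]] += beta * z
        true_effects.append({"covariate": None, "chemical": chem, "beta": beta})
    for eff, entry in zip(config.covariate_effects, true_effects):
        entry["covariate"] = eff.covariate

    x = 10.0 ** logx
    x[x < loq[None, :]] = 0.0

    pid = list(cov_full.index)
    sample_id = pd.Index([f"{p}:week12" for p in pid], name="sample_id")
    start_dates = [_random_date_in_season(s, rng) for s in cov_full["season"]]
    samples = pd.DataFrame(
        {
            "participant_id": pid,
            "timepoint": "week12",
            "batch": batches,
            "start_date": start_dates,
            "duration_days": np.round(rng.normal(7.0, 0.15, n), 1),
            "gestational_age_start": cov_full["gestational_age_start"].to_numpy(),
            "wristband_size": rng.choice(["regular", "small"], size=n),
            "season": cov_full["season"].to_numpy(),
        },
        index=sample_id,
    )
    values = pd.DataFrame(x, index=sample_id, columns=chems)
    matrix = ExposureMatrix(values, samples)

    # plant MCAR missingness after the concentrations were generated
    cov_missing = cov_full.copy()
    for col, frac in config.missingness.items():
        mask = rng.random(n) < frac
        cov_missing.loc[mask, col] = pd.NA

    expected_det = {
        c: float(1 - stats.norm.cdf((np.log10(config.loq[c]) - config.log_mu[c]) / config.log_sigma[c]))
        for c in chems
    }
    truth = TruthLedger(
        seed=config.seed,
        profile_labels={p: int(k) for p, k in zip(pid, labels)},
        true_icc={
            c: (s2b / (s2b + s2w) if (s2b + s2w) > 0 else 0.0)
            for c, (s2b, s2w) in config.icc_targets.items()
        },
        true_effects=true_effects,
        expected_detection=expected_det,
    )
    records = config.chemical_records or [
        ChemicalRecord(c, c, "50-00-0", frozenset({"chemicals in commerce"})) for c in chems
    ]
    return matrix, CovariateTable(cov_missing), records, truth


def simulate_repeated(config: SimulationConfig) -> tuple[ExposureMatrix, TruthLedger]:
    """Simulate the two-timepoint repeated subsample.

    Per chemical, log10 y_it = mu + week_effect * 1[t = week24] + u_i + e_it
    with Var(u_i) = sigma2_between and Var(e_it) = sigma2_within from
    ``icc_targets``; censoring to 0 below the quantitation limit is applied
    afterwards.
    """
    if not config.icc_targets:
        raise ValueError("icc_targets must be provided for the repeated design")
    if config.n_repeated < 2:
        raise ValueError("n_repeated must be at least 2")
    rng = np.random.default_rng(config.seed + 1)
    chems = [c for c in config.chemical_ids if c in config.icc_targets]
    n = config.n_repeated
    mu = np.array([config.log_mu[c] for c in chems])
    loq = np.array([config.loq[c] for c in chems])
    s2b = np.array([config.icc_targets[c][0] for c in chems])
    s2w = np.array([config.icc_targets[c][1] for c in chems])

    u = rng.normal(0.0, 1.0, (n, len(chems))) * np.sqrt(s2b)[None, :]
    e1 = rng.normal(0.0, 1.0, (n, len(chems))) * np.sqrt(s2w)[None, :]
    e2 = rng.normal(0.0, 1.0, (n, len(chems))) * np.sqrt(s2w)[None, :]
    log1 = mu[None, :] + u + e1
    log2 = mu[None, :] + config.week_effect + u + e2
    x1, x2 = 10.0 ** log1, 10.0 ** log2
    x1[x1 < loq[None, :]] = 0.0
    x2[x2 < loq[None, :]] = 0.0

    pid = [f"P{i + 1:04d}" for i in range(n)]
    frames, metas = [], []
    for tp, x, date in (("week12", x1, _dt.date(2017, 10, 15)), ("week24", x2, _dt.date(2018, 1, 15))):
        idx = pd.Index([f"{p}:{tp}" for p in pid], name="sample_id")
        frames.append(pd.DataFrame(x, index=idx, columns=chems))
        metas.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "timepoint": tp,
                    "batch": [f"B{1 + i % config.n_batches}" for i in range(n)],
                    "start_date": date,
                    "duration_days": 7.0,
                    "gestational_age_start": 13.0 if tp == "week12" else 24.0,
                    "wristband_size": "regular",
                    "season": season_of(date),
                },
                index=idx,
            )
        )
    matrix = ExposureMatrix(pd.concat(frames), pd.concat(metas))
    truth = TruthLedger(
        seed=config.seed,
        true_icc={
            c: (config.icc_targets[c][0] / (sum(config.icc_targets[c]) or 1.0))
            for c in chems
        },
    )
    return matrix, truth
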