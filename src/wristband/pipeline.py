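"""End-to-end orchestration: simulate/load -> preprocess -> reliability ->
multiply-imputed regression -> SOM profiles, with one global seed.

Every stage writes plain CSV/JSON into the output directory and the run
closes with a ``manifest.json`` recording the seed, a hash of the resolved
configuration, and per-stage shapes, so a rerun with the same config and
seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess, reliability, mi_regression, som_profiles, synthetic_cohort
from .exposure_data import (
    ExposureMatrix,
    read_covariates,
    read_exposure_csv,
    write_covariates,
    write_exposure_csv,
    write_chemical_metadata,
)

logger = logging.getLogger("wristband")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run.

    Defaults follow the published analysis settings: a strict >60%
    detection screen, 1000 bootstrap resamples for the ICC intervals,
    25 chained-equation imputations, and SOM candidates spanning 4-25
    profiles.
    """

    out: str = "wristband_run"
    seed: int = 0
    synthetic: bool = True
    #: input file paths when synthetic is False
    exposure_path: str | None = None
    chemicals_path: str | None = None
    covariates_path: str | None = None
    repeated_path: str | None = None
    detection_threshold: float = 0.60
    icc_n_boot: int = 1000
    imputation_m: int = 25
    imputation_n_iter: int = 10
    som_epochs: int = 60
    som_candidates: list[tuple[int, int]] | None = None
    skip_reliability: bool = False
    skip_regression: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cands = raw.get("som_candidates")
        if cands is not None:
            raw["som_candidates"] = [tuple(x) for x in cands]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical_json(self) -> str:
        # the destination directory is not part of the analysis settings
        d = {k: v for k, v in dataclasses.asdict(self).items() if k != "out"}
        return json.dumps(d, sort_keys=True, default=str)


def _load_inputs(cfg: PipelineConfig, out: Path):
    if cfg.synthetic:
        sim = synthetic_cohort.default_config(seed=cfg.seed)
        matrix, cov, records, truth = synthetic_cohort.simulate_cohort(sim)
        repeated, rep_truth = synthetic_cohort.simulate_repeated(sim)
        write_exposure_csv(matrix, out / "exposure.csv")
        write_exposure_csv(repeated, out / "exposure_repeated.csv")
        write_covariates(cov, out / "covariates.csv")
        write_chemical_metadata(records, out / "chemicals.csv")
        truth.to_json(out / "truth.json")
        return matrix, cov, records, repeated
    matrix, records = read_exposure_csv(cfg.exposure_path, cfg.chemicals_path)
    cov = read_covariates(cfg.covariates_path)
    repeated = None
    if cfg.repeated_path:
        repeated, _ = read_exposure_csv(cfg.repeated_path, cfg.chemicals_path)
    return matrix, cov, records, repeated


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest."""
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger().addHandler(handler)
    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(cfg.canonical_json().encode()).hexdigest(),
        "config": json.loads(cfg.canonical_json()),
        "stages": {},
        "outputs": [],
        "skipped": [],
    }
    try:
        matrix, cov, records, repeated = _load_inputs(cfg, out)
        week12 = matrix.subset_timepoint("week12")
        manifest["stages"]["input"] = {
            "n_samples": matrix.n_samples,
            "n_chemicals": len(matrix.chemical_ids),
        }

        # ---- preprocess ----
        det = preprocess.detection_frequency(week12)
        det.to_csv(out / "detection_summary.csv")
        filtered = preprocess.filter_by_detection(week12, cfg.detection_threshold)
        counts = preprocess.counts_per_wristband(matrix, records).loc[week12.values.index]
        counts.to_csv(out / "counts.csv")
        std = preprocess.batch_standardize(filtered)
        std.values.to_csv(out / "standardized.csv")
        manifest["stages"]["preprocess"] = {
            "n_retained_chemicals": len(filtered.chemical_ids),
            "detection_threshold": cfg.detection_threshold,
            "median_total_detects": float(counts["total"].median()),
        }

        # ---- reliability ----
        rho, rho_summary = reliability.spearman_matrix(std)
        rho.to_csv(out / "spearman.csv")
        if repeated is not None and not cfg.skip_reliability:
            icc_table = _reliability_stage(repeated, filtered.chemical_ids, cfg, out)
            manifest["stages"]["reliability"] = {
                "n_chemicals": int(len(icc_table)),
                "median_icc": float(icc_table["icc"].median()),
                "spearman_summary": rho_summary,
            }
        else:
            manifest["skipped"].append("reliability_icc")
            manifest["stages"]["reliability"] = {"spearman_summary": rho_summary}
            logger.warning("no repeated-measures data; ICC stage skipped")

        # ---- regression ----
        if not cfg.skip_regression:
            spec = mi_regression.ImputationSpec(
                m=cfg.imputation_m, n_iter=cfg.imputation_n_iter, seed=cfg.seed
            )
            suite = mi_regression.run_model_suite(std, counts, cov, spec)
            model_dir = out / "models"
            model_dir.mkdir(exist_ok=True)
            for name, pf in sorted(suite.items()):
                fname = name.replace("~", "__").replace(" ", "_").replace(",", "")
                pf.table.to_csv(model_dir / f"{fname}.csv", index=False)
            manifest["stages"]["regression"] = {"n_models": len(suite)}
        else:
            manifest["skipped"].append("regression")

        # ---- SOM profiles ----
        params = som_profiles.SOMParams(epochs=cfg.som_epochs)
        report, fit = som_profiles.select_som_size(
            std, candidates=cfg.som_candidates, params=params, seed=cfg.seed
        )
        report.table.to_csv(out / "validity.csv", index=False)
        pd.DataFrame(
            fit.grid.codebook,
            columns=std.chemical_ids,
            index=pd.Index(range(fit.grid.n_nodes), name="node"),
        ).to_csv(out / "codebook.csv")
        pd.DataFrame(
            {"sample_id": std.values.index, "profile": fit.assignment}
        ).to_csv(out / "assignments.csv", index=False)
        profile_report = som_profiles.characterize_profiles(fit, std, cov)
        _write_profile_report(profile_report, out)
        manifest["stages"]["som"] = {
            "selected_grid": list(report.selected),
            "n_grid_nodes": fit.grid.n_nodes,
            "n_occupied_profiles": fit.n_occupied,
            "quantization_error": fit.quantization_error,
            "largest_profile_share": max(
                p["share"] for p in profile_report["profiles"].values()
            ),
        }

        manifest["outputs"] = sorted(
            [str(p.relative_to(out)) for p in out.rglob("*")
             if p.is_file() and p.name != "run.log"] + ["manifest.json"]
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except Exception as exc:  # annotate the failing stage and re-raise
        done = ", ".join(manifest["stages"]) or "none"
        logger.error("pipeline failed after stage(s) [%s]: %s", done, exc)
        raise
    finally:
        logging.getLogger().removeHandler(handler)
        handler.close()


def _reliability_stage(repeated: ExposureMatrix, chemicals: list[str],
                       cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    """Standardize the repeated subsample and estimate per-chemical ICCs.

    The batch-median/z-score transform is fitted on the first-occasion
    samples and applied unchanged to the second occasion.  Chemicals that
    are constant within the first occasion (typically all-censored in the
    small subsample) cannot be standardized and are dropped with a warning.
    """
    present = [c for c in chemicals if c in repeated.chemical_ids]
    rep = repeated.subset_chemicals(present)
    week12 = rep.subset_timepoint("week12")
    sd0 = []
    vals = week12.values
    med_adj = vals - vals.groupby(week12.samples["batch"]).transform("median")
    for c in present:
        if med_adj[c].std(ddof=0) == 0:
            sd0.append(c)
    if sd0:
        warnings.warn(f"dropping constant chemical(s) in repeated subsample: {sd0}", stacklevel=2)
        rep = rep.subset_chemicals([c for c in present if c not in sd0])
        week12 = rep.subset_timepoint("week12")
    fit12 = preprocess.batch_standardize(week12)
    std_all = fit12.transform(rep)
    estimates = reliability.estimate_icc_matrix(std_all, n_boot=cfg.icc_n_boot, seed=cfg.seed)
    table, summary = reliability.classify_and_summarize(estimates)
    table.to_csv(out / "icc.csv", index=False)
    with open(out / "icc_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return table


def _write_profile_report(report: dict, out: Path) -> None:
    rows = []
    for node, p in sorted(report["profiles"].items()):
        rows.append(
            {
                "profile": node,
                "n": p["n"],
                "share": p["share"],
                "rare": p["rare"],
                "exceptional_chemicals": ";".join(p["exceptional_chemicals"]),
            }
        )
    pd.DataFrame(rows).to_csv(out / "profile_report.csv", index=False)
    serializable = {
        "n_samples": report["n_samples"],
        "n_grid_nodes": report["n_grid_nodes"],
        "n_occupied": report["n_occupied"],
        "rare_profiles": report["rare_profiles"],
        "profiles": {
            str(k): {
                "n": p["n"],
                "share": p["share"],
                "rare": p["rare"],
                "exceptional_chemicals": p["exceptional_chemicals"],
                "median_standardized": {c: round(float(v), 6) for c, v in p["median_standardized"].items()},
                **({"covariates": p["covariates"]} if "covariates" in p else {}),
            }
            for k, p in report["profiles"].items()
        },
    }
    with open(out / "profile_report.json", "w") as fh:
        json.dump(serializable, fh, indent=1, sort_keys=True)
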