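"""Detection screening, per-wristband counts, and batch-median standardization.

All analyses downstream of the raw concentration matrix work on a common
transform: subtract each chemical's batch-specific median, then z-score the
result per chemical to mean 0 and SD 1 over all samples in the fit.  The
median subtraction removes additive analytical-batch offsets; the global
scaling puts chemicals with very different concentration ranges on a common
footing for correlation, regression and clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure_data import CATEGORIES, ChemicalRecord, ExposureMatrix

__all__ = [
    "StandardizedMatrix",
    "detection_frequency",
    "filter_by_detection",
    "counts_per_wristband",
    "batch_standardize",
]


@dataclass
class StandardizedMatrix:
    """Unitless standardized concentrations plus the fitted transform.

    ``batch_medians`` (batch x chemical), ``center`` and ``scale`` (per
    chemical) are retained so the transform fitted on one set of samples
    (e.g. the ~12-week wristbands) can be applied unchanged to another
    (e.g. the ~24-week repeats).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    batch_medians: pd.DataFrame
    center: pd.Series
    scale: pd.Series

    @property
    def chemical_ids(self) -> list[str]:
        return list(self.values.columns)

    def transform(self, matrix: ExposureMatrix) -> "StandardizedMatrix":
        """Apply this fitted transform to new samples.

        Samples from batches unseen in the fit fall back to the chemical's
        median across fitted batches.
        """
        chems = self.chemical_ids
        vals = matrix.values[chems].copy()
        fallback = self.batch_medians.median(axis=0)
        for b, idx in matrix.samples.groupby("batch").groups.items():
            med = self.batch_medians.loc[b] if b in self.batch_medians.index else fallback
            vals.loc[idx] = vals.loc[idx] - med
        z = (vals - self.center) / self.scale
        return StandardizedMatrix(z, matrix.samples.copy(), self.batch_medians, self.center, self.scale)


def detection_frequency(matrix: ExposureMatrix) -> pd.DataFrame:
    """Per-chemical detection fraction, median and IQR of the concentration.

    A detect is any concentration > 0.  Medians and quartiles are computed
    over all samples, zeros included, with linear-interpolation quantiles;
    this is why sub-75%-detected chemicals show a lower quartile of 0.
    """
    if matrix.n_samples == 0:
        raise ValueError("empty exposure matrix")
    v = matrix.values
    out = pd.DataFrame(
        {
            "detection_fraction": (v > 0).mean(axis=0),
            "median": v.median(axis=0),
            "q1": v.quantile(0.25, axis=0),
            "q3": v.quantile(0.75, axis=0),
        }
    )
    out.index.name = "chemical_id"
    return out


def filter_by_detection(matrix: ExposureMatrix, threshold: float = 0.60) -> ExposureMatrix:
    """Restrict to chemicals detected in strictly more than ``threshold`` of samples.

    The inequality is strict: a chemical detected in exactly 60% of
    wristbands does not survive the default screen.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    frac = (matrix.values > 0).mean(axis=0)
    keep = [c for c in matrix.chemical_ids if frac[c] > threshold]
    if not keep:
        warnings.warn("detection filter removed every chemical", stacklevel=2)
    return matrix.subset_chemicals(keep)


def counts_per_wristband(
    matrix: ExposureMatrix, chemicals: list[ChemicalRecord]
) -> pd.DataFrame:
    """Per-sample total detected chemicals and per-category detect counts.

    A chemical belonging to k categories contributes once to each of those
    k category counts but only once to the total.
    """
    by_id = {r.chemical_id: r for r in chemicals}
    missing = [c for c in matrix.chemical_ids if c not in by_id]
    if missing:
        raise KeyError(f"chemicals without metadata: {missing}")
    detected = (matrix.values > 0)
    out = pd.DataFrame({"total": detected.sum(axis=1)})
    for cat in sorted(CATEGORIES):
        members = [c for c in matrix.chemical_ids if cat in by_id[c].categories]
        out[cat] = detected[members].sum(axis=1) if members else 0
    return out


def batch_standardize(matrix: ExposureMatrix) -> StandardizedMatrix:
    """Fit the batch-median + z-score transform on ``matrix``.

    v' = v - median_batch(chemical); z = (v' - mean(v')) / SD(v') with the
    sample SD pooled over batches (the z-scoring convention of R's
    ``scale``).  Constant chemicals (zero SD after median adjustment) are
    rejected by name.
    """
    vals = matrix.values.copy()
    medians = vals.groupby(matrix.samples["batch"]).median()
    medians.index.name = "batch"
    for b, idx in matrix.samples.groupby("batch").groups.items():
        vals.loc[idx] = vals.loc[idx] - medians.loc[b]
    center = vals.mean(axis=0)
    scale = vals.std(axis=0, ddof=1)
    zero = scale[scale == 0]
    if len(zero):
        raise ValueError(f"constant chemical(s) after batch adjustment: {list(zero.index)}")
    z = (vals - center) / scale
    return StandardizedMatrix(z, matrix.samples.copy(), medians, center, scale)
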