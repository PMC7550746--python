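"""Reference panel of frequently detected wristband chemicals.

Seventeen organic chemicals that a week-long silicone-wristband deployment
in a prospective pregnancy cohort (n = 255 at ~12 gestational weeks, with a
20-participant repeat at ~24 weeks) detected in a majority of samplers.
For each chemical the panel carries the early-pregnancy detection
percentage, the median and interquartile range of the concentration
(ng/g silicone, non-detects counted as 0), the between-timepoint intraclass
correlation with its bootstrap 95% CI, and the screening panel's category
memberships.

The panel serves two purposes: it provides hand-checkable inputs for the
detection-filter, reliability-classification and category-bookkeeping
worked examples, and it anchors the synthetic cohort generator's default
detection frequencies and concentration magnitudes to realistic values.
"""

from __future__ import annotations

import pandas as pd

from .exposure_data import ChemicalRecord

__all__ = ["reference_panel", "reference_chemicals"]

# name, CASN, %detected (12wk), median, q1, q3, %detected (24wk),
# icc, icc_lo, icc_hi, categories
_PANEL = [
    ("Di-n-butyl phthalate", "84-74-2", 99, 4580, 2440, 8490, 100, 0.09, 0.00, 0.50,
     "chemicals in commerce;personal care products;pesticides"),
    ("Galaxolide", "1222-05-5", 98, 6930, 2380, 16000, 90, 0.58, 0.26, 0.75,
     "chemicals in commerce;personal care products"),
    ("Diisobutyl phthalate", "84-69-5", 97, 4810, 2445, 8335, 80, 0.62, 0.14, 0.78,
     "chemicals in commerce"),
    ("Butyl benzyl phthalate", "85-68-7", 94, 2650, 1115, 8230, 80, 0.59, 0.00, 0.83,
     "chemicals in commerce"),
    ("Lilial", "80-54-6", 90, 1150, 332, 2895, 90, 0.69, 0.27, 0.93,
     "personal care products"),
    ("Benzyl salicylate", "118-58-1", 89, 5050, 1755, 12800, 95, 0.13, 0.00, 0.49,
     "personal care products"),
    ("Tonalide", "1506-02-1", 83, 297, 76, 1065, 80, 0.68, 0.27, 0.91,
     "personal care products"),
    ("N,N-Diethyl-m-toluamide", "134-62-3", 83, 715, 196, 1710, 95, 0.03, 0.00, 0.47,
     "pesticides"),
    ("Benzophenone", "119-61-9", 82, 220, 104, 422, 80, 0.22, 0.00, 0.78,
     "chemicals in commerce;personal care products"),
    ("Ethylene brassylate", "105-95-3", 82, 4580, 592, 13600, 90, 0.22, 0.04, 0.79,
     "personal care products"),
    ("Benzyl benzoate", "120-51-4", 82, 2570, 763, 8840, 85, 0.09, 0.00, 0.57,
     "pesticides"),
    ("Di-n-nonyl phthalate", "84-76-4", 67, 662, 0, 2415, 70, 0.13, 0.00, 0.62,
     "chemicals in commerce"),
    ("Permethrin", "52645-53-1", 67, 265, 0, 1285, 70, 0.08, 0.00, 0.54,
     "pesticides"),
    ("Diethyl phthalate", "84-66-2", 64, 777, 0, 2520, 100, 0.14, 0.00, 0.55,
     "chemicals in commerce;pesticides"),
    ("Butylated hydroxyanisole", "25013-16-5", 64, 72, 0, 174, 10, 0.00, 0.00, 0.10,
     "personal care products;pharmacological"),
    ("2,4-Di-tert-butylphenol", "96-76-4", 61, 203, 0, 972, 60, 0.22, 0.00, 0.77,
     "chemicals in commerce"),
    ("Triphenyl phosphate", "115-86-6", 58, 163, 0, 580, 75, 0.33, 0.00, 0.58,
     "chemicals in commerce;flame retardants"),
]

_COLUMNS = [
    "name", "casn", "pct_detected_12wk", "median_12wk", "q1_12wk", "q3_12wk",
    "pct_detected_24wk", "icc", "icc_ci_low", "icc_ci_high", "categories",
]


def reference_panel() -> pd.DataFrame:
    """The reference panel as a DataFrame indexed by chemical name."""
    df = pd.DataFrame(_PANEL, columns=_COLUMNS).set_index("name")
    return df


def reference_chemicals() -> list[ChemicalRecord]:
    """The panel as validated :class:`ChemicalRecord` objects.

    ``chemical_id`` is the chemical name.
    """
    return [
        ChemicalRecord(
            chemical_id=row[0],
            name=row[0],
            casn=row[1],
            categories=frozenset(row[10].split(";")),
        )
        for row in _PANEL
    ]
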