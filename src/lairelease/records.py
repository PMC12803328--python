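"""Formulation records: the 11 static material descriptors of an LAI.

One record describes a drug-loaded PLGA microparticle formulation by the
descriptors used throughout the package: the emulsion method, drug
physicochemistry (MW, TPSA, LogP), carrier polymer properties (MW, LA/GA
molar ratio), formulation composition (initial drug-to-polymer ratio,
encapsulation efficiency, loading capacity, solubility-enhancer
concentration) and particle size.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

#: Canonical internal (snake_case) names of the 11 descriptors, in order.
FEATURE_COLUMNS = [
    "formulation_method",
    "drug_mw",
    "drug_tpsa",
    "drug_logp",
    "polymer_mw",
    "la_ga_ratio",
    "initial_dpr",
    "particle_size",
    "encapsulation_efficiency",
    "loading_capacity",
    "solubility_enhancer_conc",
]

#: Mapping from internal names to the display names used in data files.
DISPLAY_NAMES = {
    "formulation_method": "Formulation Method",
    "drug_mw": "Drug MW",
    "drug_tpsa": "Drug TPSA",
    "drug_logp": "Drug LogP",
    "polymer_mw": "Polymer MW",
    "la_ga_ratio": "LA/GA",
    "initial_dpr": "Initial DPR",
    "particle_size": "Particle Size",
    "encapsulation_efficiency": "Encapsulation Efficiency",
    "loading_capacity": "Loading Capacity",
    "solubility_enhancer_conc": "Solubility Enhancer Conc.",
}

#: The one categorical descriptor and its known levels.
CATEGORICAL_COLUMNS = ["formulation_method"]
FORMULATION_METHODS = [
    "oil-in-water",
    "water-in-oil-in-water",
    "spray-drying",
    "coacervation",
]

CONTINUOUS_COLUMNS = [c for c in FEATURE_COLUMNS if c not in CATEGORICAL_COLUMNS]


@dataclass(frozen=True)
class FormulationRecord:
    """One formulation's 11 static material descriptors.

    Units: drug_mw in Da, drug_tpsa in A^2, polymer_mw in kDa, la_ga_ratio
    dimensionless (lactide:glycolide molar ratio), initial_dpr as a weight
    ratio, particle_size in um, encapsulation_efficiency and
    loading_capacity in percent, solubility_enhancer_conc in percent w/v.
    """

    formulation_id: str
    formulation_method: str
    drug_mw: float
    drug_tpsa: float
    drug_logp: float
    polymer_mw: float
    la_ga_ratio: float
    initial_dpr: float
    particle_size: float
    encapsulation_efficiency: float
    loading_capacity: float
    solubility_enhancer_conc: float


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate records as a DataFrame with formulation_id + the 11 columns."""
    rows = [
        {f.name: getattr(r, f.name) for f in fields(FormulationRecord)}
        for r in records
    ]
    return pd.DataFrame(rows, columns=["formulation_id"] + FEATURE_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[FormulationRecord]:
    """Inverse of :func:`records_to_frame`."""
    return [
        FormulationRecord(
            formulation_id=str(row["formulation_id"]),
            **{c: row[c] for c in FEATURE_COLUMNS},
        )
        for _, row in df.iterrows()
    ]
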