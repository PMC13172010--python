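"""Metabolic-health and obesity phenotype assignment.

Implements the BioSHaRE-EU Healthy Obese Project metabolic-health criteria
(fasting glucose, triglycerides, sex-specific HDL, blood pressure, plus
diagnosis/medication overrides) crossed with the WHO BMI obesity threshold
to yield MHNO / MHO / MUNO / MUO labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolicLabel",
    "PhenotypeLabel",
    "PhenotypeCriteria",
    "SubjectRecord",
    "classify_metabolic_health",
    "classify_phenotype",
    "classify_table",
]

# unit conversion factors: mmol/L -> mg/dL
GLUCOSE_MMOL_TO_MGDL = 18.0
TG_MMOL_TO_MGDL = 88.57
HDL_MMOL_TO_MGDL = 38.67


class MetabolicLabel(str, Enum):
    MH = "MH"
    MU = "MU"
    INDETERMINATE = "indeterminate"


class PhenotypeLabel(str, Enum):
    MHNO = "MHNO"
    MHO = "MHO"
    MUNO = "MUNO"
    MUO = "MUO"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class PhenotypeCriteria:
    """Thresholds for metabolic health (all in mg/dL, mmHg, kg/m²).

    Metabolic health requires glucose <= glucose_max, TG <= tg_max,
    HDL strictly above the sex-specific minimum, SBP <= sbp_max and
    DBP <= dbp_max; obesity is BMI >= bmi_obesity (inclusive).
    """

    glucose_max: float = 100.0
    tg_max: float = 150.0
    hdl_min_male: float = 40.0
    hdl_min_female: float = 50.0
    sbp_max: float = 130.0
    dbp_max: float = 85.0
    bmi_obesity: float = 30.0
    # native mmol/L thresholds; the dual-unit bounds are not numerically
    # equivalent under the standard conversion factors, so mmol records are
    # judged against these rather than converted
    glucose_max_mmol: float = 6.1
    tg_max_mmol: float = 1.7
    hdl_min_male_mmol: float = 1.0
    hdl_min_female_mmol: float = 1.3


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's biomarkers and diagnosis flags; any field may be missing.

    Numeric units default to mg/dL (biochemistry), mmHg (pressure) and kg/m²
    (BMI); set ``units='mmol'`` if glucose/TG/HDL are given in mmol/L.
    """

    glucose: Optional[float] = None
    triglycerides: Optional[float] = None
    hdl: Optional[float] = None
    sex: Optional[str] = None  # 'male' | 'female'
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    bmi: Optional[float] = None
    diagnosed_t2d: bool = False
    diagnosed_hypertension: bool = False
    diagnosed_hypercholesterolemia: bool = False
    on_medication: bool = False
    impaired_glucose_tolerance: bool = False
    units: str = "mgdl"  # 'mgdl' | 'mmol'

    def __post_init__(self) -> None:
        for name in ("glucose", "triglycerides", "hdl", "sbp", "dbp", "bmi"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.units not in ("mgdl", "mmol"):
            raise ValueError("units must be 'mgdl' or 'mmol'")

    def in_mgdl(self) -> "SubjectRecord":
        if self.units == "mgdl":
            return self
        conv = {
            "glucose": GLUCOSE_MMOL_TO_MGDL,
            "triglycerides": TG_MMOL_TO_MGDL,
            "hdl": HDL_MMOL_TO_MGDL,
        }
        updates = {
            k: (getattr(self, k) * f if getattr(self, k) is not None else None)
            for k, f in conv.items()
        }
        import dataclasses

        return dataclasses.replace(self, units="mgdl", **updates)


def classify_metabolic_health(
    record: SubjectRecord, criteria: PhenotypeCriteria = PhenotypeCriteria()
) -> MetabolicLabel:
    """MU if any diagnosis/medication/IGT flag is set; else MH iff every
    biomarker satisfies its bound; indeterminate when a needed field is missing.
    """
    if (
        record.diagnosed_t2d
        or record.diagnosed_hypertension
        or record.diagnosed_hypercholesterolemia
        or record.on_medication
        or record.impaired_glucose_tolerance
    ):
        return MetabolicLabel.MU

    r = record
    if r.units == "mmol":
        glucose_max, tg_max = criteria.glucose_max_mmol, criteria.tg_max_mmol
        hdl_min_m, hdl_min_f = criteria.hdl_min_male_mmol, criteria.hdl_min_female_mmol
    else:
        glucose_max, tg_max = criteria.glucose_max, criteria.tg_max
        hdl_min_m, hdl_min_f = criteria.hdl_min_male, criteria.hdl_min_female
    checks: list[Optional[bool]] = []

    def bound(value: Optional[float], ok) -> Optional[bool]:
        return None if value is None else ok(value)

    checks.append(bound(r.glucose, lambda v: v <= glucose_max))
    checks.append(bound(r.triglycerides, lambda v: v <= tg_max))
    if r.hdl is not None:
        if r.sex is None:
            logger.warning("HDL present but sex missing; cannot apply sex-specific bound")
            checks.append(None)
        else:
            hdl_min = hdl_min_m if r.sex == "male" else hdl_min_f
            checks.append(r.hdl > hdl_min)  # strict ">"
    else:
        checks.append(None)
    checks.append(bound(r.sbp, lambda v: v <= criteria.sbp_max))
    checks.append(bound(r.dbp, lambda v: v <= criteria.dbp_max))

    if any(c is False for c in checks):
        return MetabolicLabel.MU  # a single failed biomarker is enough
    if any(c is None for c in checks):
        return MetabolicLabel.INDETERMINATE
    return MetabolicLabel.MH


def classify_phenotype(
    record: SubjectRecord, criteria: PhenotypeCriteria = PhenotypeCriteria()
) -> PhenotypeLabel:
    """Cross of metabolic-health label × obesity (BMI >= threshold, inclusive)."""
    if record.bmi is None:
        return PhenotypeLabel.INDETERMINATE
    mh = classify_metabolic_health(record, criteria)
    if mh is MetabolicLabel.INDETERMINATE:
        return PhenotypeLabel.INDETERMINATE
    obese = record.bmi >= criteria.bmi_obesity
    if mh is MetabolicLabel.MH:
        return PhenotypeLabel.MHO if obese else PhenotypeLabel.MHNO
    return PhenotypeLabel.MUO if obese else PhenotypeLabel.MUNO


_COLUMN_MAP = {
    "glucose": "glucose",
    "triglycerides": "triglycerides",
    "hdl": "hdl",
    "sex": "sex",
    "sbp": "sbp",
    "dbp": "dbp",
    "bmi": "bmi",
    "diagnosed_t2d": "diagnosed_t2d",
    "diagnosed_hypertension": "diagnosed_hypertension",
    "diagnosed_hypercholesterolemia": "diagnosed_hypercholesterolemia",
    "on_medication": "on_medication",
    "impaired_glucose_tolerance": "impaired_glucose_tolerance",
}


def classify_table(
    metadata: pd.DataFrame,
    criteria: PhenotypeCriteria = PhenotypeCriteria(),
    units: str = "mgdl",
) -> pd.Series:
    """Classify every row of a metadata table; returns a phenotype Series.

    Recognized columns follow the :class:`SubjectRecord` field names; missing
    columns are treated as missing fields (flags default to False).
    """
    labels = []
    for _, row in metadata.iterrows():
        kwargs = {}
        for col, fieldname in _COLUMN_MAP.items():
            if col in metadata.columns and pd.notna(row[col]):
                v = row[col]
                if fieldname.startswith(("diagnosed", "on_", "impaired")):
                    v = bool(v)
                elif fieldname != "sex":
                    v = float(v)
                kwargs[fieldname] = v
        rec = SubjectRecord(units=units, **kwargs)
        labels.append(classify_phenotype(rec, criteria).value)
    out = pd.Series(labels, index=metadata.index, name="phenotype")
    n_ind = int((out == "indeterminate").sum())
    if n_ind:
        logger.info("%d subject(s) classified as indeterminate", n_ind)
    return out
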