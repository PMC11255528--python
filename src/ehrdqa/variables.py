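"""Registry of the 28 chart-abstraction variables.

Each patient record is abstracted twice — once from the paper chart and
once from the EHR — over a fixed set of 28 variables covering enrollment
in HIV care, antiretroviral (ART) regimens, drug pickups, and the last
three viral-load (VL) results.  Fifteen of the 28 enter the per-record
concordance score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class VariableKind(enum.Enum):
    DATE = "date"
    CATEGORICAL = "categorical"
    DRUG_REGIMEN = "drug_regimen"
    VIRAL_LOAD = "viral_load"
    DEMOGRAPHIC = "demographic"


@dataclass(frozen=True)
class VariableSpec:
    """Static description of one abstracted variable.

    Attributes
    ----------
    name :
        Canonical snake_case identifier used in file headers
        (``paper_<name>`` / ``ehr_<name>`` columns).
    kind :
        Value type driving missingness and match rules.
    in_concordance :
        Whether the variable is one of the 15 scored for concordance.
    repeated :
        True for the repeated series (drug pickups 1-3, viral loads 1-3).
    hiv_epoch_bound :
        Date variables tied to HIV treatment: values before the start of
        HIV care delivery in the country are implausible and treated as
        missing.  Date of birth instead uses its own plausibility window.
    """

    name: str
    kind: VariableKind
    in_concordance: bool = False
    repeated: bool = False
    hiv_epoch_bound: bool = False


_K = VariableKind

#: The 28 variables, in chart-abstraction order.
VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("date_of_birth", _K.DATE, in_concordance=True),
    VariableSpec("gender", _K.DEMOGRAPHIC, in_concordance=True),
    VariableSpec("district", _K.CATEGORICAL),
    VariableSpec("sector", _K.CATEGORICAL),
    VariableSpec("facility_name", _K.CATEGORICAL),
    VariableSpec("date_last_visit", _K.DATE, in_concordance=True),
    VariableSpec("date_first_positive_test", _K.DATE, in_concordance=True,
                 hiv_epoch_bound=True),
    VariableSpec("date_enrollment", _K.DATE, in_concordance=True,
                 hiv_epoch_bound=True),
    VariableSpec("date_first_art", _K.DATE, in_concordance=True,
                 hiv_epoch_bound=True),
    VariableSpec("who_stage", _K.CATEGORICAL, in_concordance=True),
    VariableSpec("regimen1_start_date", _K.DATE, in_concordance=True,
                 hiv_epoch_bound=True),
    VariableSpec("regimen1_drugs", _K.DRUG_REGIMEN, in_concordance=True),
    VariableSpec("regimen2_start_date", _K.DATE, in_concordance=True,
                 hiv_epoch_bound=True),
    VariableSpec("regimen2_drugs", _K.DRUG_REGIMEN, in_concordance=True),
    VariableSpec("regimen3_start_date", _K.DATE, hiv_epoch_bound=True),
    VariableSpec("regimen3_drugs", _K.DRUG_REGIMEN),
    VariableSpec("pickup1_date", _K.DATE, in_concordance=True, repeated=True,
                 hiv_epoch_bound=True),
    VariableSpec("pickup1_drugs", _K.DRUG_REGIMEN, in_concordance=True,
                 repeated=True),
    VariableSpec("pickup2_date", _K.DATE, repeated=True, hiv_epoch_bound=True),
    VariableSpec("pickup2_drugs", _K.DRUG_REGIMEN, repeated=True),
    VariableSpec("pickup3_date", _K.DATE, repeated=True, hiv_epoch_bound=True),
    VariableSpec("pickup3_drugs", _K.DRUG_REGIMEN, repeated=True),
    VariableSpec("vl1_date", _K.DATE, in_concordance=True, repeated=True,
                 hiv_epoch_bound=True),
    VariableSpec("vl1_value", _K.VIRAL_LOAD, in_concordance=True, repeated=True),
    VariableSpec("vl2_date", _K.DATE, repeated=True, hiv_epoch_bound=True),
    VariableSpec("vl2_value", _K.VIRAL_LOAD, repeated=True),
    VariableSpec("vl3_date", _K.DATE, repeated=True, hiv_epoch_bound=True),
    VariableSpec("vl3_value", _K.VIRAL_LOAD, repeated=True),
)

VARIABLE_NAMES: tuple[str, ...] = tuple(v.name for v in VARIABLES)
SPEC_BY_NAME: dict[str, VariableSpec] = {v.name: v for v in VARIABLES}
CONCORDANCE_VARIABLES: tuple[VariableSpec, ...] = tuple(
    v for v in VARIABLES if v.in_concordance
)

# sanity checks on the registry itself
assert len(VARIABLES) == 28
assert len(CONCORDANCE_VARIABLES) == 15
assert sum(1 for v in CONCORDANCE_VARIABLES
           if v.kind is _K.DATE and v.name != "date_of_birth") == 8


def get_spec(name: str) -> VariableSpec:
    """Look up a variable by name, raising a helpful error for typos."""
    try:
        return SPEC_BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown variable {name!r}; expected one of {VARIABLE_NAMES}"
        ) from None
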