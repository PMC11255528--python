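"""Missing-value rules and value standardization.

All metrics downstream compare *standardized* values.  A field counts as
missing if it is blank, carries a coded "not available" answer, or — for
dates — is implausible: a known sentinel (data-entry conventions often
substitute 1980-01-01 for an unknown date), a date after the chart was
abstracted, or an HIV-treatment date before HIV care existed in the
country.  Matching is exact after kind-specific standardization: drug
regimens are canonicalized to an order-free component list, viral loads
match within 1 copy/mL (EHR forms store whole numbers while lab reports
may carry a decimal), and dates must agree exactly.
"""

from __future__ import annotations

import datetime
import re
import unicodedata
from dataclasses import dataclass, field

from .variables import VariableKind, VariableSpec

__all__ = [
    "RawValue",
    "MissingnessConfig",
    "CanonicalRegimen",
    "canonicalize_regimen",
    "is_missing",
    "values_match",
    "vl_values_match",
    "VL_MATCH_TOLERANCE",
]

#: Absolute tolerance, in copies/mL, under which two viral loads match.
VL_MATCH_TOLERANCE = 1.0

DEFAULT_NA_CODES = frozenset({"unknown", "n/a", "na", "not available"})


def _parse_date(text: str) -> datetime.date | None:
    try:
        return datetime.date.fromisoformat(text.strip())
    except ValueError:
        return None


def _parse_number(text: str) -> float | None:
    try:
        return float(text.strip())
    except ValueError:
        return None


def _norm_text(text: str) -> str:
    """Case-fold, strip accents, collapse whitespace."""
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    return " ".join(text.casefold().split())


@dataclass(frozen=True)
class RawValue:
    """One abstracted field value: the raw text plus its typed parse.

    Parsing never raises; malformed text simply fails to parse and the
    value is then treated as missing by :func:`is_missing`.
    """

    text: str
    kind: VariableKind

    @property
    def parsed(self) -> datetime.date | float | str | None:
        text = self.text.strip()
        if not text:
            return None
        if self.kind is VariableKind.DATE:
            return _parse_date(text)
        if self.kind is VariableKind.VIRAL_LOAD:
            return _parse_number(text)
        return text


@dataclass(frozen=True)
class MissingnessConfig:
    """Plausibility windows and sentinel codes for missingness decisions.

    Parameters
    ----------
    collection_date :
        When the charts were abstracted; any later date is impossible.
    hiv_epoch :
        Lower bound for HIV-treatment-related dates (enrollment, ART
        start, regimen starts, pickups, viral loads).
    sentinel_dates :
        Placeholder dates that encode "unknown".
    na_codes :
        Case-insensitive coded answers meaning "not available".
    dob_floor :
        Lower plausibility bound for date of birth.
    """

    collection_date: datetime.date = datetime.date(2018, 12, 1)
    hiv_epoch: datetime.date = datetime.date(2002, 1, 1)
    sentinel_dates: frozenset[datetime.date] = frozenset(
        {datetime.date(1980, 1, 1)}
    )
    na_codes: frozenset[str] = DEFAULT_NA_CODES
    dob_floor: datetime.date = datetime.date(1900, 1, 1)
    regimen_synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.hiv_epoch < self.collection_date:
            raise ValueError("hiv_epoch must precede collection_date")


DEFAULT_MISSINGNESS = MissingnessConfig()


def is_missing(
    value: RawValue | str,
    spec: VariableSpec,
    cfg: MissingnessConfig = DEFAULT_MISSINGNESS,
) -> bool:
    """Decide whether a field counts as missing.

    Total over arbitrary text: blank, coded-NA, unparseable, sentinel
    and out-of-window dates are all missing; everything else is present.
    """
    if isinstance(value, str):
        value = RawValue(value, spec.kind)
    text = value.text.strip()
    if not text:
        return True
    if _norm_text(text) in cfg.na_codes:
        return True
    parsed = value.parsed
    if spec.kind is VariableKind.DATE:
        if parsed is None:
            return True
        if parsed in cfg.sentinel_dates:
            return True
        if parsed > cfg.collection_date:
            return True
        if spec.hiv_epoch_bound and parsed < cfg.hiv_epoch:
            return True
        if spec.name == "date_of_birth" and parsed < cfg.dob_floor:
            return True
        return False
    if spec.kind is VariableKind.VIRAL_LOAD:
        return parsed is None
    return False


# --- drug-regimen canonicalization -------------------------------------

_SEP_RE = re.compile(r"\s*(?:\+|,|;|/|\band\b)\s*", flags=re.IGNORECASE)
_COMPONENT_RE = re.compile(r"^(?P<name>.*?)\s*\(\s*(?P<dose>[\d.]+)\s*\)\s*$")


@dataclass(frozen=True)
class CanonicalRegimen:
    """Order-free canonical form of a drug-regimen string.

    ``components`` is a sorted tuple of ``(drug, dose)`` pairs — a
    multiset, so a repeated component is preserved.  Components whose
    dose could not be parsed carry ``dose=None`` and compare by their
    normalized text alone.
    """

    components: tuple[tuple[str, float | None], ...]

    def render(self) -> str:
        parts = []
        for name, dose in self.components:
            if dose is None:
                parts.append(name)
            else:
                parts.append(f"{name} ({dose:g})")
        return " + ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def canonicalize_regimen(
    raw: str, synonyms: dict[str, str] | None = None
) -> CanonicalRegimen:
    """Canonicalize a regimen string to a sorted component multiset.

    Separator dialect ("+", "and", commas, semicolons, slashes) and
    component order never affect the result; canonicalization is
    idempotent under :meth:`CanonicalRegimen.render`.  Drug names are
    case-folded, accent-stripped and whitespace-collapsed; an optional
    synonym map rewrites normalized names (e.g. spelling variants).  No
    fuzzy matching is attempted.
    """
    synonyms = synonyms or {}
    components: list[tuple[str, float | None]] = []
    for token in _SEP_RE.split(raw):
        token = token.strip()
        if not token:
            continue
        m = _COMPONENT_RE.match(token)
        if m:
            name = _norm_text(m.group("name"))
            dose: float | None = float(m.group("dose"))
        else:
            name = _norm_text(token)
            dose = None
        name = synonyms.get(name, name)
        if name:
            components.append((name, dose))
    key = lambda c: (c[0], c[1] is not None, c[1] if c[1] is not None else 0.0)
    return CanonicalRegimen(tuple(sorted(components, key=key)))


def vl_values_match(a: float, b: float) -> bool:
    """Two viral loads match within 1 copy/mL (symmetric)."""
    return abs(a - b) <= VL_MATCH_TOLERANCE


def values_match(
    a: RawValue | str,
    b: RawValue | str,
    spec: VariableSpec,
    cfg: MissingnessConfig = DEFAULT_MISSINGNESS,
) -> bool:
    """Exact equality after kind-specific standardization.

    Callers are expected to have screened both sides with
    :func:`is_missing`; a missing side never matches.
    """
    if isinstance(a, str):
        a = RawValue(a, spec.kind)
    if isinstance(b, str):
        b = RawValue(b, spec.kind)
    if is_missing(a, spec, cfg) or is_missing(b, spec, cfg):
        return False
    if spec.kind is VariableKind.DATE:
        return a.parsed == b.parsed
    if spec.kind is VariableKind.VIRAL_LOAD:
        return vl_values_match(a.parsed, b.parsed)  # type: ignore[arg-type]
    if spec.kind is VariableKind.DRUG_REGIMEN:
        syn = cfg.regimen_synonyms
        return canonicalize_regimen(a.text, syn) == canonicalize_regimen(b.text, syn)
    return _norm_text(a.text) == _norm_text(b.text)
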