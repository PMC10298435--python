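"""Drug reference tables and medicine-name standardisation.

Three external knowledge sources drive the risk scores:

* an anticholinergic-burden (ACB) table mapping each anticholinergic drug to
  a risk class 1 (lowest) to 3 (highest);
* a pairwise interaction-severity table mapping unordered drug pairs to a
  severity 1 (mild), 2 (moderate) or 3 (severe);
* a component map that expands combination medicines (and brand synonyms)
  into their constituent drugs so that prescriptions and reference tables
  speak the same vocabulary.

All tables are plain delimited text with one header row.  Matching is
deterministic: names are case-folded, trimmed and internal whitespace is
collapsed; no fuzzy matching is attempted, so every lookup is auditable.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

logger = logging.getLogger(__name__)

VALID_CLASSES = frozenset({1, 2, 3})
VALID_SEVERITIES = frozenset({1, 2, 3})


class TableValidationError(ValueError):
    """A reference table violates its schema (bad value, duplicate, self-pair)."""


def canonical(name: str) -> str:
    """Canonical form of a drug or medicine name.

    Case-folds, strips, and collapses internal whitespace runs to a single
    space.  Idempotent.
    """
    return " ".join(str(name).split()).casefold()


def _read_rows(path: Path | str, delimiter: str = ",") -> Iterator[tuple[int, dict]]:
    """Yield (line_number, row_dict) for each data row of a delimited file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reference table not found: {path}")
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        if reader.fieldnames is None:
            raise TableValidationError(f"{path}: empty file, expected a header row")
        for lineno, row in enumerate(reader, start=2):
            yield lineno, row


def _require_columns(path: Path | str, row: dict, columns: Sequence[str], lineno: int) -> None:
    for column in columns:
        if row.get(column) is None or str(row[column]).strip() == "":
            raise TableValidationError(f"{path}: line {lineno}: missing value for column {column!r}")


@dataclass(frozen=True)
class AcbTable:
    """Anticholinergic-burden classes keyed by canonical drug name."""

    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {d: c for d, c in self.entries.items() if c not in VALID_CLASSES}
        if bad:
            raise TableValidationError(f"ACB classes outside {{1,2,3}}: {bad}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, drug: str) -> bool:
        return canonical(drug) in self.entries

    def class_of(self, drug: str) -> int | None:
        return self.entries.get(canonical(drug))

    def score(self, drug: str) -> int:
        """Per-drug contribution to WARS: the class score, or 0 if unlisted."""
        return self.entries.get(canonical(drug), 0)

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(self.entries)


def load_acb_table(
    path: Path | str,
    *,
    name_col: str = "drug",
    class_col: str = "acb_class",
    delimiter: str = ",",
) -> AcbTable:
    """Load and validate an ACB table from delimited text.

    Rows whose class is not an integer in {1,2,3} raise
    :class:`TableValidationError` naming the offending line, as does a drug
    listed twice with conflicting classes.  Repeated identical rows collapse.
    """
    entries: dict[str, int] = {}
    for lineno, row in _read_rows(path, delimiter):
        _require_columns(path, row, (name_col, class_col), lineno)
        name = canonical(row[name_col])
        try:
            acb_class = int(str(row[class_col]).strip())
        except ValueError as exc:
            raise TableValidationError(
                f"{path}: line {lineno}: ACB class {row[class_col]!r} is not an integer"
            ) from exc
        if acb_class not in VALID_CLASSES:
            raise TableValidationError(
                f"{path}: line {lineno}: ACB class must be 1, 2 or 3, got {acb_class}"
            )
        if name in entries and entries[name] != acb_class:
            raise TableValidationError(
                f"{path}: line {lineno}: drug {name!r} listed with conflicting classes "
                f"{entries[name]} and {acb_class}"
            )
        entries[name] = acb_class
    return AcbTable(entries)


def _pair(a: str, b: str) -> tuple[str, str]:
    """Unordered canonical pair key (sorted 2-tuple)."""
    ca, cb = canonical(a), canonical(b)
    return (ca, cb) if ca <= cb else (cb, ca)


@dataclass(frozen=True)
class InteractionTable:
    """Pairwise interaction severities keyed by unordered canonical drug pair.

    Lookup is symmetric and a pair absent from the table reads as 0 (no
    listed interaction).
    """

    entries: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        for (a, b), severity in self.entries.items():
            if a == b:
                raise TableValidationError(f"self-interaction pair not allowed: {a!r}")
            if severity not in VALID_SEVERITIES:
                raise TableValidationError(
                    f"severity for pair ({a!r}, {b!r}) must be 1, 2 or 3, got {severity}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def severity(self, a: str, b: str) -> int:
        ca, cb = canonical(a), canonical(b)
        if ca == cb:
            return 0
        return self.entries.get(_pair(a, b), 0)

    def pairs(self) -> Iterator[tuple[str, str, int]]:
        for (a, b), severity in self.entries.items():
            yield a, b, severity

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(d for pair in self.entries for d in pair)


def load_interaction_table(
    path: Path | str,
    *,
    a_col: str = "drug_a",
    b_col: str = "drug_b",
    severity_col: str = "severity",
    delimiter: str = ",",
) -> InteractionTable:
    """Load a symmetric interaction table; (a,b) and (b,a) collapse to one entry.

    Self-pairs and conflicting severities for the same unordered pair raise
    :class:`TableValidationError` with the line number.
    """
    entries: dict[tuple[str, str], int] = {}
    for lineno, row in _read_rows(path, delimiter):
        _require_columns(path, row, (a_col, b_col, severity_col), lineno)
        a, b = canonical(row[a_col]), canonical(row[b_col])
        if a == b:
            raise TableValidationError(f"{path}: line {lineno}: self-pair {a!r} is not allowed")
        try:
            severity = int(str(row[severity_col]).strip())
        except ValueError as exc:
            raise TableValidationError(
                f"{path}: line {lineno}: severity {row[severity_col]!r} is not an integer"
            ) from exc
        if severity not in VALID_SEVERITIES:
            raise TableValidationError(
                f"{path}: line {lineno}: severity must be 1, 2 or 3, got {severity}"
            )
        key = _pair(a, b)
        if key in entries and entries[key] != severity:
            raise TableValidationError(
                f"{path}: line {lineno}: pair {key} listed with conflicting severities "
                f"{entries[key]} and {severity}"
            )
        entries[key] = severity
    return InteractionTable(entries)


@dataclass(frozen=True)
class ComponentMap:
    """Expansion of medicine names into constituent drugs.

    One medicine maps to a non-empty tuple of component drug names; medicines
    absent from the map are treated as single-component drugs under their own
    canonical name.
    """

    entries: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for medicine, components in self.entries.items():
            if not components:
                raise TableValidationError(f"medicine {medicine!r} maps to no components")

    def __len__(self) -> int:
        return len(self.entries)

    def components(self, medicine: str) -> tuple[str, ...]:
        name = canonical(medicine)
        return self.entries.get(name, (name,))


def load_component_map(
    path: Path | str,
    *,
    medicine_col: str = "medicine",
    component_col: str = "component",
    delimiter: str = ",",
) -> ComponentMap:
    """Load a component map stored as one (medicine, component) row per component."""
    entries: dict[str, list[str]] = {}
    for lineno, row in _read_rows(path, delimiter):
        _require_columns(path, row, (medicine_col, component_col), lineno)
        medicine = canonical(row[medicine_col])
        component = canonical(row[component_col])
        entries.setdefault(medicine, [])
        if component not in entries[medicine]:
            entries[medicine].append(component)
    return ComponentMap({m: tuple(c) for m, c in entries.items()})


class StandardizedDrugs(NamedTuple):
    """Outcome of standardisation: the drug set plus the unresolvable subset."""

    drugs: frozenset[str]
    unknown: frozenset[str]


def standardize(
    medicines: Iterable[str],
    components: ComponentMap | None = None,
    known: Iterable[str] | None = None,
) -> StandardizedDrugs:
    """Standardise raw medicine names into a deduplicated set of component drugs.

    Each medicine is canonicalised and expanded through ``components``;
    medicines absent from the map pass through as their own canonical name.
    When ``known`` (the vocabulary of the reference tables) is given, expanded
    drugs not in it are retained in the output but flagged as unknown and
    logged — they will simply contribute 0 to both risk scores.  Idempotent
    and order-independent.
    """
    components = components or ComponentMap({})
    drugs: set[str] = set()
    for medicine in medicines:
        name = canonical(medicine)
        if not name:
            continue
        drugs.update(components.components(name))
    known_set = {canonical(k) for k in known} if known is not None else None
    if known_set is None:
        unknown: frozenset[str] = frozenset()
    else:
        unknown = frozenset(d for d in drugs if d not in known_set)
        if unknown:
            logger.debug("standardize: %d drug name(s) not in any reference table: %s",
                         len(unknown), ", ".join(sorted(unknown)))
    return StandardizedDrugs(frozenset(drugs), unknown)
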