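"""Prescription extracts, cohort construction, and the end-to-end pipeline.

The pipeline mirrors how the scores are used operationally: parse a
prescription extract, keep only patients with active prescriptions,
standardise medicine names, score every patient, drop zero-score patients,
and cluster each of three analysis cohorts —

* ``wars``  — patients with WARS > 0, clustered on WARS alone;
* ``wirs``  — patients with WIRS > 0, clustered on WIRS alone;
* ``joint`` — the intersection (both scores positive), clustered on the
  2-D (WARS, WIRS) vector;

then rank the clusters into risk groups and colour-tier them.  Intermediate
per-patient scores are persisted to a cache file so clustering can be re-run
(e.g. with a different quantile) without re-scoring the population.
"""

from __future__ import annotations

import csv
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .clustering import FeatureMatrix, RiskGrouping, cluster_risk_profiles
from .knowledge import (
    AcbTable,
    ComponentMap,
    InteractionTable,
    canonical,
    load_acb_table,
    load_component_map,
    load_interaction_table,
    standardize,
)
from .scoring import PatientRecord, RiskProfile, score_population

logger = logging.getLogger(__name__)

COHORT_CATEGORIES = ("wars", "wirs", "joint")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


@dataclass(frozen=True)
class PrescriptionRow:
    patient_id: str
    medicine: str
    status: str


@dataclass(frozen=True)
class PrescriptionExtract:
    """Parsed prescription rows plus provenance and parse diagnostics."""

    rows: tuple[PrescriptionRow, ...]
    source: str
    n_malformed: int = 0

    def __len__(self) -> int:
        return len(self.rows)

    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for row in self.rows:
            seen.setdefault(row.patient_id, None)
        return list(seen)


def load_prescriptions(
    path: Path | str,
    *,
    patient_col: str = "patient_id",
    medicine_col: str = "medicine",
    status_col: str = "status",
    delimiter: str = ",",
) -> PrescriptionExtract:
    """Parse a prescription extract from delimited text.

    Rows missing a patient id or medicine name are counted and logged, never
    fatal; a file with zero valid rows is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"[load] prescription file not found: {path}")
    rows: list[PrescriptionRow] = []
    n_malformed = 0
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        if reader.fieldnames is None:
            raise PipelineError(f"[load] {path}: empty file")
        for lineno, row in enumerate(reader, start=2):
            patient = str(row.get(patient_col) or "").strip()
            medicine = str(row.get(medicine_col) or "").strip()
            if not patient or not medicine:
                n_malformed += 1
                logger.warning("%s: line %d: malformed row skipped", path, lineno)
                continue
            status = str(row.get(status_col) or "").strip()
            rows.append(PrescriptionRow(patient, medicine, status))
    if not rows:
        raise PipelineError(f"[load] {path}: no valid prescription rows")
    return PrescriptionExtract(tuple(rows), source=str(path), n_malformed=n_malformed)


def filter_active(
    extract: PrescriptionExtract,
    components: ComponentMap | None = None,
    known: Iterable[str] | None = None,
    active_values: Sequence[str] = ("active",),
) -> tuple[list[PatientRecord], dict[str, frozenset[str]]]:
    """Keep patients with at least one active prescription row.

    Returns the standardised records (insertion order of first appearance)
    plus, per patient, the drugs that could not be resolved against the
    reference tables (for the audit log).  Ceased-only patients are dropped;
    for the rest, only their active rows contribute drugs.
    """
    truthy = {canonical(v) for v in active_values}
    by_patient: dict[str, list[str]] = {}
    for row in extract.rows:
        if canonical(row.status) in truthy:
            by_patient.setdefault(row.patient_id, []).append(row.medicine)
    records: list[PatientRecord] = []
    unknown_by_patient: dict[str, frozenset[str]] = {}
    for patient_id, medicines in by_patient.items():
        drugs, unknown = standardize(medicines, components, known)
        records.append(PatientRecord(patient_id, drugs))
        if unknown:
            unknown_by_patient[patient_id] = unknown
    if unknown_by_patient:
        logger.warning(
            "filter_active: %d patient(s) carry drug names absent from the reference tables "
            "(they contribute 0 to both scores; details in the audit log)",
            len(unknown_by_patient),
        )
    return records, unknown_by_patient


@dataclass(frozen=True)
class CohortSpec:
    """One analysis cohort: category plus its member risk profiles."""

    category: str
    profiles: tuple[RiskProfile, ...]

    def __post_init__(self) -> None:
        if self.category not in COHORT_CATEGORIES:
            raise ValueError(f"unknown cohort category {self.category!r}")
        for profile in self.profiles:
            if self.category in ("wars", "joint") and profile.wars <= 0:
                raise ValueError(f"{self.category} cohort requires wars > 0")
            if self.category in ("wirs", "joint") and profile.wirs <= 0:
                raise ValueError(f"{self.category} cohort requires wirs > 0")

    def __len__(self) -> int:
        return len(self.profiles)

    def feature_matrix(self) -> FeatureMatrix:
        ids = tuple(p.patient_id for p in self.profiles)
        if self.category == "wars":
            points = [[p.wars] for p in self.profiles]
        elif self.category == "wirs":
            points = [[p.wirs] for p in self.profiles]
        else:
            points = [[p.wars, p.wirs] for p in self.profiles]
        return FeatureMatrix(ids, points)


def build_cohorts(profiles: Sequence[RiskProfile]) -> dict[str, CohortSpec]:
    """Split scored patients into the three analysis cohorts.

    Zero scores are excluded per category, so a patient with both scores
    zero appears in no cohort and the joint cohort is exactly the
    intersection of the other two.
    """
    wars = tuple(p for p in profiles if p.wars > 0)
    wirs = tuple(p for p in profiles if p.wirs > 0)
    joint = tuple(p for p in profiles if p.wars > 0 and p.wirs > 0)
    return {
        "wars": CohortSpec("wars", wars),
        "wirs": CohortSpec("wirs", wirs),
        "joint": CohortSpec("joint", joint),
    }


# -- configuration ----------------------------------------------------------


@dataclass
class PipelineConfig:
    """Run configuration for the end-to-end pipeline.

    Either the four input paths are given, or ``synthetic`` holds a
    population-spec mapping and the inputs are generated (and written to
    ``output_dir/inputs`` for audit).
    """

    output_dir: Path
    prescriptions: Path | None = None
    acb: Path | None = None
    interactions: Path | None = None
    components: Path | None = None
    synthetic: Mapping | None = None
    quantile: float = 0.3
    scale: bool = False
    tier_fractions: tuple[float, float] = (1.0 / 3.0, 1.0 / 3.0)
    active_values: tuple[str, ...] = ("active",)
    seed: int = 0
    columns: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: Path | str, **overrides) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        raw.update(overrides)
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "PipelineConfig":
        kwargs = dict(raw)
        for key in ("output_dir", "prescriptions", "acb", "interactions", "components"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        if "tier_fractions" in kwargs and kwargs["tier_fractions"] is not None:
            kwargs["tier_fractions"] = tuple(float(v) for v in kwargs["tier_fractions"])
        if "active_values" in kwargs and kwargs["active_values"] is not None:
            kwargs["active_values"] = tuple(str(v) for v in kwargs["active_values"])
        return cls(**kwargs)


@dataclass(frozen=True)
class CohortResult:
    category: str
    size: int
    grouping: RiskGrouping | None  # None when the cohort is empty


@dataclass(frozen=True)
class PipelineReport:
    """Summary of one pipeline run plus the paths of everything written."""

    n_rows: int
    n_malformed: int
    n_active_patients: int
    n_zero_score_excluded: int
    n_all_unknown: int
    cohorts: dict[str, CohortResult]
    outputs: dict[str, Path]


# -- output writers ---------------------------------------------------------


def write_scores(profiles: Sequence[RiskProfile], path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("patient_id,wars,wirs\n")
        for p in profiles:
            fh.write(f"{p.patient_id},{p.wars},{p.wirs}\n")


def read_scores(path: Path | str) -> list[RiskProfile]:
    """Read a score cache written by :func:`write_scores`."""
    profiles = []
    with Path(path).open(newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            profiles.append(RiskProfile(row["patient_id"], int(row["wars"]), int(row["wirs"])))
    return profiles


def _write_clusters(cohort: CohortSpec, grouping: RiskGrouping, path: Path) -> None:
    by_id = {p.patient_id: p for p in cohort.profiles}
    tier_of = {g.rank: g.tier for g in grouping.groups}
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("patient_id,wars,wirs,group_rank,tier\n")
        for patient_id, rank in zip(grouping.patient_ids, grouping.labels):
            p = by_id[patient_id]
            fh.write(f"{patient_id},{p.wars},{p.wirs},{rank},{tier_of[rank]}\n")


def grouping_summary(grouping: RiskGrouping) -> dict:
    return {
        "bandwidth": grouping.bandwidth,
        "n_patients": len(grouping.patient_ids),
        "n_groups": grouping.n_groups,
        "groups": [
            {
                "rank": g.rank,
                "size": g.size,
                "mean_risk": list(g.mean_risk),
                "score_range": [list(r) for r in g.score_range],
                "center": list(g.center),
                "tier": g.tier,
            }
            for g in grouping.groups
        ],
    }


def check_partition(grouping: RiskGrouping, n_expected: int) -> None:
    """Assert that group sizes sum to the cohort size (a hard invariant)."""
    total = sum(g.size for g in grouping.groups)
    if total != n_expected:
        raise PipelineError(
            f"[report] partition violated: group sizes sum to {total}, cohort has {n_expected}"
        )


def format_report(report: PipelineReport) -> str:
    """Human-readable run summary with one group table per cohort.

    Each table is shaped (rank, number of patients, average risk per group);
    the joint cohort additionally lists per-group WARS/WIRS means.
    """
    lines = [
        "polyrisk pipeline report",
        "========================",
        f"prescription rows: {report.n_rows} (malformed skipped: {report.n_malformed})",
        f"patients with active prescriptions: {report.n_active_patients}",
        f"patients excluded with zero scores: {report.n_zero_score_excluded}"
        + (f" (of which all-unknown drugs: {report.n_all_unknown})" if report.n_all_unknown else ""),
        "",
    ]
    for category in COHORT_CATEGORIES:
        result = report.cohorts[category]
        lines.append(f"cohort {category!r}: {result.size} patient(s)")
        if result.grouping is None:
            lines.append("  empty cohort: no patients with a positive score; nothing to cluster")
            lines.append("")
            continue
        grouping = result.grouping
        lines.append(f"  bandwidth: {grouping.bandwidth:.6g}   groups: {grouping.n_groups}")
        if category == "joint":
            lines.append("  rank  size  mean_wars  mean_wirs  tier")
            for g in grouping.groups:
                lines.append(
                    f"  {g.rank:>4}  {g.size:>4}  {g.mean_risk[0]:>9.2f}  {g.mean_risk[1]:>9.2f}  {g.tier}"
                )
        else:
            lines.append("  rank  size  mean_risk  range        tier")
            for g in grouping.groups:
                lo, hi = g.score_range[0]
                lines.append(
                    f"  {g.rank:>4}  {g.size:>4}  {g.mean_risk[0]:>9.2f}  {lo:g}-{hi:<9g} {g.tier}"
                )
        lines.append("")
    return "\n".join(lines) + "\n"


# -- pipeline ---------------------------------------------------------------


def cluster_cohorts(
    cohorts: Mapping[str, CohortSpec],
    quantile: float = 0.3,
    tier_fractions: tuple[float, float] = (1.0 / 3.0, 1.0 / 3.0),
    scale: bool = False,
) -> dict[str, CohortResult]:
    """Cluster, rank and tier each non-empty cohort; verify the partition."""
    results: dict[str, CohortResult] = {}
    for category, cohort in cohorts.items():
        if len(cohort) == 0:
            results[category] = CohortResult(category, 0, None)
            continue
        grouping = cluster_risk_profiles(
            cohort.feature_matrix(), quantile=quantile, tier_fractions=tier_fractions, scale=scale
        )
        check_partition(grouping, len(cohort))
        results[category] = CohortResult(category, len(cohort), grouping)
    return results


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full flow: load -> filter -> standardise -> score ->
    cohorts -> cluster -> rank -> tier -> report.

    Writes the score cache, per-cohort cluster assignments and group
    summaries, an audit log and a human-readable report under
    ``config.output_dir``.  Any stage failure removes partial outputs and
    raises :class:`PipelineError` labelled with the stage.
    """
    output_dir = Path(config.output_dir)
    created = not output_dir.exists()
    output_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_pipeline(config, output_dir, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        if created:
            shutil.rmtree(output_dir, ignore_errors=True)
        raise


def _run_pipeline(config: PipelineConfig, output_dir: Path, written: list[Path]) -> PipelineReport:
    cols = dict(config.columns)
    outputs: dict[str, Path] = {}

    # -- stage: inputs
    if config.synthetic is not None:
        from .synthetic import (
            PopulationSpec,
            generate_knowledge_base,
            generate_population,
            write_knowledge_base,
            write_prescriptions,
        )

        spec = PopulationSpec.from_mapping(dict(config.synthetic, seed=config.seed))
        kb = generate_knowledge_base(spec)
        extract = generate_population(spec, kb)
        inputs_dir = output_dir / "inputs"
        kb_paths = write_knowledge_base(kb, inputs_dir)
        presc_path = inputs_dir / "prescriptions.csv"
        write_prescriptions(extract, presc_path)
        written.extend([*kb_paths.values(), presc_path])
        acb, interactions, components = kb
    else:
        if not (config.prescriptions and config.acb and config.interactions):
            raise PipelineError("[load] config must name prescription, ACB and interaction files "
                                "or request synthetic generation")
        try:
            acb = load_acb_table(
                config.acb,
                name_col=cols.get("acb_name", "drug"),
                class_col=cols.get("acb_class", "acb_class"),
            )
            interactions = load_interaction_table(config.interactions)
            components = (
                load_component_map(config.components) if config.components else ComponentMap({})
            )
        except Exception as exc:
            raise PipelineError(f"[load] reference tables: {exc}") from exc
        extract = load_prescriptions(
            config.prescriptions,
            patient_col=cols.get("patient_id", "patient_id"),
            medicine_col=cols.get("medicine", "medicine"),
            status_col=cols.get("status", "status"),
        )

    # -- stage: filter + standardise
    known = acb.drugs | interactions.drugs
    records, unknown_by_patient = filter_active(
        extract, components, known, active_values=config.active_values
    )

    # -- stage: score (persisted as the re-clusterable cache)
    profiles = score_population(records, acb, interactions)
    scores_path = output_dir / "scores.csv"
    write_scores(profiles, scores_path)
    written.append(scores_path)
    outputs["scores"] = scores_path

    # -- stage: cohorts + clustering
    cohorts = build_cohorts(profiles)
    n_zero = len(profiles) - len(
        {p.patient_id for c in cohorts.values() for p in c.profiles}
    )
    all_unknown = sum(
        1
        for record in records
        if record.drugs and record.drugs == unknown_by_patient.get(record.patient_id, frozenset())
    )
    results = cluster_cohorts(
        cohorts,
        quantile=config.quantile,
        tier_fractions=config.tier_fractions,
        scale=config.scale,
    )

    # -- stage: report
    for category, result in results.items():
        if result.grouping is None:
            continue
        clusters_path = output_dir / f"clusters_{category}.csv"
        _write_clusters(cohorts[category], result.grouping, clusters_path)
        written.append(clusters_path)
        outputs[f"clusters_{category}"] = clusters_path
        groups_path = output_dir / f"groups_{category}.json"
        with groups_path.open("w", encoding="utf-8", newline="\n") as fh:
            json.dump(grouping_summary(result.grouping), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(groups_path)
        outputs[f"groups_{category}"] = groups_path

    audit_path = output_dir / "audit.log"
    with audit_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"source: {extract.source}\n")
        fh.write(f"malformed rows skipped: {extract.n_malformed}\n")
        fh.write(f"patients with all drugs unknown: {all_unknown}\n")
        for patient_id in sorted(unknown_by_patient):
            fh.write(
                f"unknown drugs for {patient_id}: "
                f"{', '.join(sorted(unknown_by_patient[patient_id]))}\n"
            )
    written.append(audit_path)
    outputs["audit"] = audit_path

    report = PipelineReport(
        n_rows=len(extract),
        n_malformed=extract.n_malformed,
        n_active_patients=len(records),
        n_zero_score_excluded=n_zero,
        n_all_unknown=all_unknown,
        cohorts=results,
        outputs=outputs,
    )
    report_path = output_dir / "report.txt"
    report_path.write_text(format_report(report), encoding="utf-8")
    written.append(report_path)
    outputs["report"] = report_path
    return report
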