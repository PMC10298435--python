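"""Synthetic knowledge bases and prescription populations.

No real patient data can ship with the package, so every stage is exercised
on generated populations with controllable score structure.  The default
specification emulates a primary-care population in which anticholinergic
prescribing is uncommon (about 6.2% of patients carry a positive WARS) and
listed drug–drug interactions are rarer still (about 3% of patients carry a
positive WIRS), with heavily right-skewed scores: most positive-score
patients sit at the bottom of the scale and a handful of extreme outliers
form the small high-risk clusters the method is designed to surface.

Reproducibility: each generator operation draws from its own random stream,
derived from ``spec.seed`` and a CRC-32 hash of the operation name, so
adding new operations never perturbs existing outputs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np

from .cohort import PrescriptionExtract, PrescriptionRow
from .knowledge import AcbTable, ComponentMap, InteractionTable

KnowledgeBase = tuple[AcbTable, InteractionTable, ComponentMap]


class SpecValidationError(ValueError):
    """A population specification violates its invariants."""


def _rng(seed: int, op_name: str) -> np.random.Generator:
    """Independent stream per generator operation, stable across versions."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(op_name.encode())]))


@dataclass(frozen=True)
class PopulationSpec:
    """Controls for the synthetic knowledge base and population.

    ``drugs_per_patient`` is a distribution descriptor mapping:
    ``{"kind": "poisson", "mean": m, "min": k}``,
    ``{"kind": "uniform", "low": a, "high": b}`` or
    ``{"kind": "fixed", "value": k}``.
    """

    n_patients: int = 10_000
    anticholinergic_prevalence: float = 0.062
    # With drug counts 1 + Poisson(3), E[#unordered pairs per patient] = 7.5,
    # so a listed-pair density of 0.004 yields ~3% of patients WIRS-positive.
    interaction_density: float = 0.004
    class_mix: tuple[float, float, float] = (0.5, 0.2, 0.3)
    severity_mix: tuple[float, float, float] = (0.3, 0.4, 0.3)
    drugs_per_patient: Mapping = field(
        default_factory=lambda: {"kind": "poisson", "mean": 4.0, "min": 1}
    )
    n_drugs_in_kb: int = 200
    acb_fraction: float = 0.3
    extra_acb_mean: float = 0.6
    ceased_row_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0 or self.n_drugs_in_kb < 1:
            raise SpecValidationError("n_patients must be >= 0 and n_drugs_in_kb >= 1")
        for name in ("anticholinergic_prevalence", "interaction_density",
                     "acb_fraction", "ceased_row_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SpecValidationError(f"{name} must be a fraction in [0, 1], got {value}")
        for name in ("class_mix", "severity_mix"):
            mix = getattr(self, name)
            if len(mix) != 3 or any(p < 0 for p in mix):
                raise SpecValidationError(f"{name} needs 3 non-negative probabilities")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise SpecValidationError(f"{name} must sum to 1 within 1e-9, got {sum(mix)}")
        kind = self.drugs_per_patient.get("kind")
        if kind not in ("poisson", "uniform", "fixed"):
            raise SpecValidationError(f"unknown drugs_per_patient kind {kind!r}")

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "PopulationSpec":
        kwargs = dict(raw)
        for name in ("class_mix", "severity_mix"):
            if name in kwargs and kwargs[name] is not None:
                kwargs[name] = tuple(float(v) for v in kwargs[name])
        return cls(**kwargs)


def _drug_names(n: int) -> list[str]:
    return [f"drug_{i:04d}" for i in range(n)]


def _draw_counts(descriptor: Mapping, rng: np.random.Generator, n: int) -> np.ndarray:
    kind = descriptor["kind"]
    if kind == "fixed":
        return np.full(n, int(descriptor["value"]), dtype=int)
    if kind == "uniform":
        return rng.integers(int(descriptor["low"]), int(descriptor["high"]) + 1, size=n)
    minimum = int(descriptor.get("min", 0))
    mean = float(descriptor["mean"])
    return minimum + rng.poisson(max(mean - minimum, 0.0), size=n)


def generate_knowledge_base(spec: PopulationSpec) -> KnowledgeBase:
    """Generate (ACB table, interaction table, component map) from a spec.

    A random ``acb_fraction`` subset of the drug vocabulary receives ACB
    classes drawn from ``class_mix``; every unordered drug pair is listed
    with probability ``interaction_density`` and given a severity from
    ``severity_mix``.  A small set of combination medicines mapping to two
    component drugs each exercises name standardisation.
    """
    spec.validate()
    names = _drug_names(spec.n_drugs_in_kb)

    rng = _rng(spec.seed, "acb")
    n_acb = int(round(spec.acb_fraction * spec.n_drugs_in_kb))
    acb_drugs = sorted(rng.choice(names, size=n_acb, replace=False))
    classes = rng.choice([1, 2, 3], size=n_acb, p=spec.class_mix)
    acb = AcbTable(dict(zip(acb_drugs, (int(c) for c in classes))))

    rng = _rng(spec.seed, "interactions")
    entries: dict[tuple[str, str], int] = {}
    pairs = list(combinations(names, 2))
    listed = rng.random(len(pairs)) < spec.interaction_density
    severities = rng.choice([1, 2, 3], size=len(pairs), p=spec.severity_mix)
    for pair, is_listed, severity in zip(pairs, listed, severities):
        if is_listed:
            entries[pair] = int(severity)
    interactions = InteractionTable(entries)

    rng = _rng(spec.seed, "components")
    n_combo = spec.n_drugs_in_kb // 20
    combo_entries: dict[str, tuple[str, ...]] = {}
    for i in range(n_combo):
        parts = rng.choice(names, size=2, replace=False)
        combo_entries[f"mix_{i:03d}"] = tuple(sorted(str(p) for p in parts))
    components = ComponentMap(combo_entries)
    return acb, interactions, components


def generate_population(spec: PopulationSpec, kb: KnowledgeBase) -> PrescriptionExtract:
    """Generate an active-prescription population over a knowledge base.

    Exactly a Binomial(n, prevalence) share of patients is flagged
    anticholinergic and receives at least one ACB-listed drug (one plus a
    small Poisson excess, yielding the right-skewed WARS distribution);
    unflagged patients draw only from non-ACB drugs so the WARS-positive
    fraction is controlled exactly.  All rows are active unless
    ``ceased_row_fraction`` injects additional historical (ceased) rows.
    """
    spec.validate()
    acb, _interactions, _components = kb
    names = _drug_names(spec.n_drugs_in_kb)
    acb_drugs = sorted(acb.entries)
    non_acb = [n for n in names if n not in acb.entries]
    if not non_acb:
        raise SpecValidationError("knowledge base has no non-anticholinergic drugs")

    rng = _rng(spec.seed, "population")
    totals = np.maximum(_draw_counts(spec.drugs_per_patient, rng, spec.n_patients), 1)
    flagged = rng.random(spec.n_patients) < spec.anticholinergic_prevalence
    n_extra = rng.poisson(spec.extra_acb_mean, size=spec.n_patients)

    rows: list[PrescriptionRow] = []
    for i in range(spec.n_patients):
        patient_id = f"pt_{i:06d}"
        total = int(totals[i])
        chosen: list[str] = []
        if flagged[i] and acb_drugs:
            k_acb = min(1 + int(n_extra[i]), len(acb_drugs), total)
            chosen.extend(str(d) for d in rng.choice(acb_drugs, size=k_acb, replace=False))
        n_rest = min(total - len(chosen), len(non_acb))
        if n_rest > 0:
            chosen.extend(str(d) for d in rng.choice(non_acb, size=n_rest, replace=False))
        for drug in chosen:
            rows.append(PrescriptionRow(patient_id, drug, "active"))
        if rng.random() < spec.ceased_row_fraction:
            ceased = rng.choice(names, size=1 + int(rng.integers(0, 2)), replace=False)
            for drug in ceased:
                rows.append(PrescriptionRow(patient_id, str(drug), "ceased"))
    return PrescriptionExtract(tuple(rows), source=f"synthetic(seed={spec.seed})")


# -- delimited-text writers (same dialects the loaders consume) -------------


def write_knowledge_base(kb: KnowledgeBase, directory: Path | str) -> dict[str, Path]:
    acb, interactions, components = kb
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "acb": directory / "acb.csv",
        "interactions": directory / "interactions.csv",
        "components": directory / "components.csv",
    }
    with paths["acb"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("drug,acb_class\n")
        for drug in sorted(acb.entries):
            fh.write(f"{drug},{acb.entries[drug]}\n")
    with paths["interactions"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("drug_a,drug_b,severity\n")
        for a, b in sorted(interactions.entries):
            fh.write(f"{a},{b},{interactions.entries[(a, b)]}\n")
    with paths["components"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("medicine,component\n")
        for medicine in sorted(components.entries):
            for component in components.entries[medicine]:
                fh.write(f"{medicine},{component}\n")
    return paths


def write_prescriptions(extract: PrescriptionExtract, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("patient_id,medicine,status\n")
        for row in extract.rows:
            fh.write(f"{row.patient_id},{row.medicine},{row.status}\n")
    return path
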