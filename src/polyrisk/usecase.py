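"""Bundled worked example: one real-shaped patient and their reference tables.

A single patient prescribed twelve medicines, together with the exact
anticholinergic-burden rows and severe interaction pairs needed to score
them.  Five of the medicines are anticholinergic (three class-3, two
class-1), giving WARS = 3+3+3+1+1 = 11; the interaction table lists
seventeen severe pairs among the twelve drugs, giving WIRS = 17*3 = 51.
The fixture is version-pinned: these constants never change.
"""

from __future__ import annotations

from pathlib import Path

from .cohort import PrescriptionExtract, PrescriptionRow
from .knowledge import AcbTable, ComponentMap, InteractionTable

PATIENT_ID = "usecase-patient"

MEDICINES: tuple[str, ...] = (
    "Betamethasone",
    "Citalopram",
    "Clarithromycin",
    "Quinine",
    "Sildenafil",
    "Diclofenac",
    "Omeprazole",
    "Amitriptyline",
    "Hydroxyzine",
    "Promethazine",
    "Cetirizine",
    "Codeine",
)

ACB_ROWS: tuple[tuple[str, int], ...] = (
    ("amitriptyline", 3),
    ("hydroxyzine", 3),
    ("promethazine", 3),
    ("cetirizine", 1),
    ("codeine", 1),
)

# The seventeen severe unordered interaction pairs among the patient's drugs.
SEVERE_PAIRS: tuple[tuple[str, str], ...] = (
    ("betamethasone", "citalopram"),
    ("betamethasone", "clarithromycin"),
    ("betamethasone", "diclofenac"),
    ("betamethasone", "hydroxyzine"),
    ("betamethasone", "quinine"),
    ("betamethasone", "sildenafil"),
    ("citalopram", "clarithromycin"),
    ("citalopram", "hydroxyzine"),
    ("citalopram", "omeprazole"),
    ("citalopram", "quinine"),
    ("citalopram", "sildenafil"),
    ("clarithromycin", "hydroxyzine"),
    ("clarithromycin", "quinine"),
    ("clarithromycin", "sildenafil"),
    ("hydroxyzine", "quinine"),
    ("hydroxyzine", "sildenafil"),
    ("quinine", "sildenafil"),
)


def usecase_fixture() -> tuple[PrescriptionExtract, AcbTable, InteractionTable]:
    """The worked-example patient plus the tables that score them."""
    rows = tuple(
        PrescriptionRow(patient_id=PATIENT_ID, medicine=m, status="active") for m in MEDICINES
    )
    extract = PrescriptionExtract(rows=rows, source="bundled-usecase", n_malformed=0)
    acb = AcbTable(dict(ACB_ROWS))
    interactions = InteractionTable({pair: 3 for pair in SEVERE_PAIRS})
    return extract, acb, interactions


def write_usecase_fixture(directory: Path | str) -> dict[str, Path]:
    """Write the fixture as the delimited-text files the pipeline consumes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "prescriptions": directory / "prescriptions.csv",
        "acb": directory / "acb.csv",
        "interactions": directory / "interactions.csv",
        "components": directory / "components.csv",
    }
    with paths["prescriptions"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("patient_id,medicine,status\n")
        for medicine in MEDICINES:
            fh.write(f"{PATIENT_ID},{medicine},active\n")
    with paths["acb"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("drug,acb_class\n")
        for drug, acb_class in ACB_ROWS:
            fh.write(f"{drug},{acb_class}\n")
    with paths["interactions"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("drug_a,drug_b,severity\n")
        for a, b in SEVERE_PAIRS:
            fh.write(f"{a},{b},3\n")
    with paths["components"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("medicine,component\n")
    return paths


def usecase_component_map() -> ComponentMap:
    """The worked example needs no combination-medicine expansion."""
    return ComponentMap({})
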