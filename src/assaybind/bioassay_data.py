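"""Bioassay records, ChEMBL-style curation filters and pair sampling.

A bioassay is one experimental campaign measuring the affinities of several
ligands against one protein target under shared conditions.  Affinity values
within an assay are mutually comparable; values across assays carry
systematic offsets.  Pre-training therefore samples *within-assay* ligand
pairs: first an assay with probability proportional to its size, then two
distinct ligands uniformly from that assay.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MEASURE_TYPES = ("IC50", "Ki", "Kd")
TASK_TYPES = ("IC50", "K")

# The eight curation criteria, in reporting order: (name, field, accepted values)
CHEMBL_FILTERS = (
    ("standard_type", "measure_type", set(MEASURE_TYPES)),
    ("standard_relation", "relation", {"="}),
    ("standard_units", "units", {"nM"}),
    ("assay_type", "assay_type", {"B"}),
    ("target_type", "target_type", {"SINGLE PROTEIN"}),
    ("component_type", "component_type", {"PROTEIN"}),
    ("molecule_type", "molecule_type", {"Small molecule"}),
    ("bao_format", "bao_format", {"BAO_0000357"}),
)

#: CSV/TSV column names accepted by :func:`read_affinity_table`.
TABLE_COLUMNS = (
    "assay_id", "target_id", "ligand_id", "standard_type", "standard_relation",
    "standard_value", "standard_units", "assay_type", "target_type",
    "component_type", "molecule_type", "bao_format",
)


class UnsupportedLabelError(ValueError):
    pass


class TieExhaustionError(RuntimeError):
    """An assay's values are all equal; no rankable pair exists."""


@dataclass
class AffinityRecord:
    """One experimental affinity measurement with its raw curation fields."""

    assay_id: str
    target_id: str
    ligand_id: str
    value: float  # nM
    measure_type: str
    relation: str = "="
    units: str = "nM"
    assay_type: str = "B"
    target_type: str = "SINGLE PROTEIN"
    component_type: str = "PROTEIN"
    molecule_type: str = "Small molecule"
    bao_format: str = "BAO_0000357"


@dataclass
class Bioassay:
    """A curated assay: one target, one measurement type, >= 2 ligands."""

    assay_id: str
    target_id: str
    records: list[tuple[str, float]]  # (ligand_id, value nM)
    measure_type: str

    @property
    def size(self) -> int:
        return len(self.records)


@dataclass
class BioassayPair:
    """The sampled training unit: two ligands measured in the same assay."""

    target_id: str
    ligand_a: str
    ligand_b: str
    value_a: float  # nM
    value_b: float  # nM
    measure_type: str
    task_type: str = field(init=False)
    assay_id: str = ""
    conformation_a: object | None = None
    conformation_b: object | None = None

    def __post_init__(self):
        if self.ligand_a == self.ligand_b:
            raise ValueError("pair must contain two different ligands")
        self.task_type = map_label_type(self.measure_type)


@dataclass
class CurationReport:
    """Per-criterion removal counts; every input lands in exactly one bucket."""

    input_count: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    surviving: int = 0
    surviving_by_type: dict[str, int] = field(default_factory=dict)
    assays_removed_size1: int = 0
    assays_removed_mixed_type: int = 0

    def check_conservation(self) -> bool:
        return self.input_count == self.surviving + sum(self.removed.values())

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------


def apply_chembl_filters(
    records: list[AffinityRecord],
) -> tuple[list[AffinityRecord], CurationReport]:
    """Keep records that satisfy all eight ChEMBL curation criteria.

    Criteria (applied conjunctively; removal attributed to the first failure
    in this order): measurement type in {IC50, Ki, Kd}; relation '=';
    units 'nM'; assay type 'B' (binding); target type 'SINGLE PROTEIN';
    component type 'PROTEIN'; molecule type 'Small molecule';
    BAO format 'BAO_0000357'.  A record missing a field is removed with
    reason ``missing_field``.
    """
    report = CurationReport(input_count=len(records))
    survivors: list[AffinityRecord] = []
    for rec in records:
        reason = None
        for name, attr, accepted in CHEMBL_FILTERS:
            val = getattr(rec, attr, None)
            if val is None or (isinstance(val, float) and math.isnan(val)):
                reason = "missing_field"
                break
            if val not in accepted:
                reason = name
                break
        if reason is None and not (
            isinstance(rec.value, (int, float)) and math.isfinite(rec.value) and rec.value > 0
        ):
            reason = "nonpositive_value"
        if reason is None:
            survivors.append(rec)
        else:
            report.removed[reason] = report.removed.get(reason, 0) + 1
    report.surviving = len(survivors)
    for rec in survivors:
        report.surviving_by_type[rec.measure_type] = (
            report.surviving_by_type.get(rec.measure_type, 0) + 1
        )
    return survivors, report


def group_into_assays(
    records: list[AffinityRecord], report: CurationReport | None = None
) -> list[Bioassay]:
    """Group curated records into bioassays.

    Assays with a single protein-ligand pair and assays spanning more than
    one affinity type are excluded.  Duplicate (assay, ligand) measurements
    collapse to their geometric-mean value.
    """
    by_assay: dict[str, list[AffinityRecord]] = {}
    for rec in records:
        by_assay.setdefault(rec.assay_id, []).append(rec)

    assays: list[Bioassay] = []
    n_size1 = n_mixed = 0
    for assay_id in sorted(by_assay):
        recs = by_assay[assay_id]
        types = {r.measure_type for r in recs}
        if len(types) > 1:
            n_mixed += 1
            continue
        # collapse duplicate ligand measurements (geometric mean, deterministic)
        by_ligand: dict[str, list[float]] = {}
        for r in recs:
            by_ligand.setdefault(r.ligand_id, []).append(r.value)
        merged = [
            (lig, float(np.exp(np.mean(np.log(vals)))))
            for lig, vals in sorted(by_ligand.items())
        ]
        if len(merged) < 2:
            n_size1 += 1
            continue
        assays.append(
            Bioassay(
                assay_id=assay_id,
                target_id=recs[0].target_id,
                records=merged,
                measure_type=next(iter(types)),
            )
        )
    if report is not None:
        report.assays_removed_size1 = n_size1
        report.assays_removed_mixed_type = n_mixed
    return assays


def map_label_type(measure_type: str) -> str:
    """Map a measurement type onto its pre-training task: IC50 stays IC50;
    Ki and Kd merge into the single K task."""
    if measure_type == "IC50":
        return "IC50"
    if measure_type in ("Ki", "Kd"):
        return "K"
    raise UnsupportedLabelError(f"unsupported measurement type: {measure_type!r}")


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def sample_assay(assays: list[Bioassay], rng: np.random.Generator) -> Bioassay:
    """Draw one assay with probability proportional to its size n_i."""
    if not assays:
        raise ValueError("no assays to sample from")
    sizes = np.array([a.size for a in assays], dtype=float)
    return assays[rng.choice(len(assays), p=sizes / sizes.sum())]


def sample_pair(
    assay: Bioassay, rng: np.random.Generator, max_retries: int = 10
) -> BioassayPair:
    """Draw two distinct ligands uniformly without replacement from an assay.

    The pair order is random.  If the two drawn values are exactly equal
    (a ranking label would be undefined) the second ligand is redrawn up to
    ``max_retries`` times, then the whole pair once more; an assay whose
    values are all identical raises :class:`TieExhaustionError`.
    """
    if assay.size < 2:
        raise ValueError("assay must contain at least two ligands")
    values = [v for _, v in assay.records]
    if len(set(values)) < 2:
        raise TieExhaustionError(
            f"assay {assay.assay_id}: all {assay.size} values equal; no rankable pair"
        )
    for _ in range(max_retries):
        i, j = rng.choice(assay.size, size=2, replace=False)
        (lig_a, val_a), (lig_b, val_b) = assay.records[i], assay.records[j]
        if val_a != val_b:
            return BioassayPair(
                target_id=assay.target_id,
                ligand_a=lig_a,
                ligand_b=lig_b,
                value_a=val_a,
                value_b=val_b,
                measure_type=assay.measure_type,
                assay_id=assay.assay_id,
            )
    # distinct values exist, so retrying cannot fail forever; one more sweep
    return sample_pair(assay, rng, max_retries)


def ranking_label(pair: BioassayPair) -> int:
    """1 iff value_a > value_b (raw nM comparison), else 0."""
    if pair.value_a == pair.value_b:
        raise ValueError("ranking label undefined for equal values")
    return int(pair.value_a > pair.value_b)


def to_paffinity(value_nm: float) -> float:
    """Convert an affinity in nM to the pAff scale: 9 - log10(value)."""
    if not value_nm > 0:
        raise ValueError(f"affinity must be positive, got {value_nm}")
    return 9.0 - math.log10(value_nm)


def from_paffinity(paff: float) -> float:
    """Inverse of :func:`to_paffinity`: nM value = 10**(9 - pAff)."""
    return 10.0 ** (9.0 - paff)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def read_affinity_table(path: str | Path) -> list[AffinityRecord]:
    """Read an affinity table (CSV or TSV by extension) into records."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        try:
            value = float(row.standard_value)
        except ValueError:
            value = math.nan
        records.append(
            AffinityRecord(
                assay_id=row.assay_id,
                target_id=row.target_id,
                ligand_id=row.ligand_id,
                value=value,
                measure_type=row.standard_type,
                relation=row.standard_relation,
                units=row.standard_units,
                assay_type=row.assay_type,
                target_type=row.target_type,
                component_type=row.component_type,
                molecule_type=row.molecule_type,
                bao_format=row.bao_format,
            )
        )
    return records


def write_affinity_table(records: list[AffinityRecord], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = [
        {
            "assay_id": r.assay_id,
            "target_id": r.target_id,
            "ligand_id": r.ligand_id,
            "standard_type": r.measure_type,
            "standard_relation": r.relation,
            "standard_value": r.value,
            "standard_units": r.units,
            "assay_type": r.assay_type,
            "target_type": r.target_type,
            "component_type": r.component_type,
            "molecule_type": r.molecule_type,
            "bao_format": r.bao_format,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS)).to_csv(path, sep=sep, index=False)
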