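"""Corpus-level reports: contingency matrix, per-category tallies, and the
structural-coverage check against a local drug-target complex table."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core_model import (
    CaseTableError,
    ClassLabel,
    MeshRootKey,
    RepositioningCase,
    parse_mesh_root_key,
)

__all__ = [
    "ContingencyMatrix",
    "StructuralCoverageReport",
    "category_tally",
    "contingency_matrix",
    "read_complex_table",
    "structural_coverage",
    "write_complex_table",
]


@dataclass
class ContingencyMatrix:
    """Counts of cases per (original, secondary) root-key pair."""

    labels: list[str]  # sorted key codes, rows == columns
    counts: dict[str, dict[str, int]]

    @property
    def diagonal_total(self) -> int:
        return sum(self.counts[k][k] for k in self.labels)

    @property
    def total(self) -> int:
        return sum(
            self.counts[r][c] for r in self.labels for c in self.labels
        )

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["original\\secondary", *self.labels])
            for row in self.labels:
                writer.writerow([row, *(self.counts[row][c] for c in self.labels)])

    def to_json_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "counts": {r: dict(self.counts[r]) for r in self.labels},
            "diagonal_total": self.diagonal_total,
            "total": self.total,
        }


def contingency_matrix(cases: Sequence[RepositioningCase]) -> ContingencyMatrix:
    """Original x secondary root-key count matrix over a corpus.

    Labels cover every key observed on either axis; each case increments
    exactly one cell, so the matrix total equals the corpus size and the
    diagonal total equals the number of same-key (disease-centric) cases.
    """
    labels = sorted(
        {c.original.mesh_key.code for c in cases}
        | {c.secondary.mesh_key.code for c in cases}
    )
    counts = {r: {c: 0 for c in labels} for r in labels}
    for case in cases:
        counts[case.original.mesh_key.code][case.secondary.mesh_key.code] += 1
    return ContingencyMatrix(labels=labels, counts=counts)


def category_tally(
    cases: Sequence[RepositioningCase],
    per_case_labels: Mapping[str, ClassLabel],
    label_filter: ClassLabel = ClassLabel.DISEASE_CENTRIC,
) -> dict[MeshRootKey, tuple[int, list[str]]]:
    """Group disease-centric cases by their shared root key.

    Returns ``{key: (count, alphabetically sorted drug names)}`` ordered by
    descending count (ties broken by key code).  Only defined for the
    disease-centric label: the other classes carry two distinct keys.
    """
    if label_filter is not ClassLabel.DISEASE_CENTRIC:
        raise ValueError(
            "category_tally is only defined for disease-centric cases; "
            f"{label_filter.value} cases have two distinct root keys"
        )
    groups: dict[MeshRootKey, list[str]] = {}
    for case in cases:
        if per_case_labels.get(case.drug_name) is not label_filter:
            continue
        groups.setdefault(case.original.mesh_key, []).append(case.drug_name)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0].code))
    return {key: (len(names), sorted(names)) for key, names in ordered}


def _norm_drug(name: str) -> str:
    return " ".join(name.split()).casefold()


def _norm_target(target_id: str) -> str:
    return target_id.strip().upper()


def read_complex_table(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a local (drug_name, target_id, structure_id) snapshot table."""
    rows: list[tuple[str, str, str]] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != [
            "drug_name",
            "target_id",
            "structure_id",
        ]:
            raise CaseTableError(
                f"complex table {path}: expected header "
                "'drug_name<TAB>target_id<TAB>structure_id'"
            )
        for i, row in enumerate(reader, start=2):
            if len(row) != 3 or not all(c.strip() for c in row):
                raise CaseTableError(
                    f"complex table {path}: malformed row {i}: {row!r}"
                )
            rows.append((row[0].strip(), row[1].strip(), row[2].strip()))
    return rows


def write_complex_table(
    rows: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["drug_name", "target_id", "structure_id"])
        writer.writerows(rows)


@dataclass
class StructuralCoverageReport:
    """Per-case availability of drug-target complex structures."""

    per_case: dict[str, dict[str, bool]]

    @property
    def n_fully_covered(self) -> int:
        return sum(1 for f in self.per_case.values() if f["fully_covered"])

    def to_json_dict(self) -> dict:
        return {
            "n_fully_covered": self.n_fully_covered,
            "per_case": {k: dict(v) for k, v in self.per_case.items()},
        }


def structural_coverage(
    cases: Sequence[RepositioningCase],
    complexes: Sequence[tuple[str, str, str]],
) -> StructuralCoverageReport:
    """Flag each case for complex availability on both indication sides.

    A side is covered when the table holds at least one structure for the
    (normalized) drug name with any target of that side; a case is fully
    covered iff both sides are.
    """
    available = {(_norm_drug(d), _norm_target(t)) for d, t, _ in complexes}
    per_case: dict[str, dict[str, bool]] = {}
    for case in cases:
        drug = _norm_drug(case.drug_name)
        has_orig = any(
            (drug, _norm_target(t.target_id)) in available
            for t in case.original_targets
        )
        has_sec = any(
            (drug, _norm_target(t.target_id)) in available
            for t in case.secondary_targets
        )
        per_case[case.drug_name] = {
            "has_original_complex": has_orig,
            "has_secondary_complex": has_sec,
            "fully_covered": has_orig and has_sec,
        }
    return StructuralCoverageReport(per_case=per_case)
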