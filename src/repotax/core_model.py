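"""Domain types and I/O for drug-target-indication repositioning corpora.

The atomic record is a :class:`RepositioningCase`: one drug together with
its original and secondary indication (each carrying a top-level MeSH
disease-category key) and the protein target sets associated with each
indication.  Case tables are tab-separated text; protein sequences live in
plain FASTA files keyed by the header token.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "CaseTableError",
    "ClassLabel",
    "Indication",
    "MeshKeyError",
    "MeshRootKey",
    "RepositioningCase",
    "SequenceStoreError",
    "TargetProtein",
    "load_case_fixture",
    "load_fixture_sequences",
    "mesh_root_key_names",
    "parse_mesh_root_key",
    "read_cases",
    "read_sequences",
    "write_cases",
    "write_sequences",
]

#: The 20 standard amino-acid letters plus the ambiguity code X.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

MODALITIES = frozenset({"small_molecule", "antibody", "protein", "other"})
MOLECULE_KINDS = frozenset({"protein", "nucleic_acid", "other", "unknown"})

CASE_TABLE_COLUMNS = (
    "drug_name",
    "modality",
    "original_label",
    "original_mesh",
    "secondary_label",
    "secondary_mesh",
    "original_targets",
    "secondary_targets",
)

_TARGET_SEP = ";"
_FIELD_SEP = "|"
_MESH_CODE_RE = re.compile(r"^[A-Z][0-9]{2}$")


class MeshKeyError(ValueError):
    """Raised for malformed MeSH tree numbers or root-category codes."""


class CaseTableError(ValueError):
    """Raised when a case table cannot be ingested."""


class SequenceStoreError(ValueError):
    """Raised for invalid FASTA input (duplicate headers, bad residues)."""


@lru_cache(maxsize=1)
def mesh_root_key_names() -> Mapping[str, str]:
    """Packaged lookup of disease-category codes to display names."""
    text = resources.files("repotax.data").joinpath("mesh_root_keys.tsv").read_text()
    names: dict[str, str] = {}
    for line in text.strip().splitlines():
        code, name = line.split("\t")
        names[code] = name
    return names


@dataclass(frozen=True, order=True)
class MeshRootKey:
    """A top-level MeSH category code, e.g. ``C04`` (Neoplasms)."""

    code: str
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not _MESH_CODE_RE.match(self.code):
            raise MeshKeyError(
                f"invalid MeSH root key {self.code!r}: expected one uppercase "
                "letter followed by two digits"
            )


def parse_mesh_root_key(raw: str) -> MeshRootKey:
    """Reduce a MeSH tree number (or bare code) to its root-category key.

    ``"C04.557"`` yields ``C04``; a bare ``"C04"`` passes through unchanged.
    The display name is filled from the packaged category lookup when the
    code is listed there, otherwise it is left empty.
    """
    if not raw or not raw.strip():
        raise MeshKeyError("empty MeSH key")
    code = raw.strip().split(".", 1)[0]
    if not _MESH_CODE_RE.match(code):
        raise MeshKeyError(
            f"cannot parse MeSH root key from {raw!r}: {code!r} does not match "
            "letter + two digits"
        )
    return MeshRootKey(code=code, name=mesh_root_key_names().get(code, ""))


@dataclass(frozen=True)
class Indication:
    """A therapeutic indication with its disease-category key."""

    label: str
    mesh_key: MeshRootKey


@dataclass(frozen=True, order=True)
class TargetProtein:
    """One therapeutic target: identifier, organism, and molecule kind.

    ``sequence_ref`` optionally names the record in a sequence store holding
    this target's amino-acid sequence; when absent, ``target_id`` itself is
    used as the lookup key.
    """

    target_id: str
    organism: str = field(default="", compare=False)
    molecule_kind: str = field(default="protein", compare=False)
    sequence_ref: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.target_id or re.search(r"\s", self.target_id):
            raise CaseTableError(
                f"invalid target identifier {self.target_id!r}: must be "
                "non-empty and contain no whitespace"
            )
        if self.molecule_kind not in MOLECULE_KINDS:
            raise CaseTableError(
                f"unknown molecule kind {self.molecule_kind!r} for target "
                f"{self.target_id}"
            )

    @property
    def sequence_key(self) -> str:
        return self.sequence_ref or self.target_id


class ClassLabel(str, Enum):
    """Repositioning category of a case."""

    DISEASE_CENTRIC = "disease_centric"
    TARGET_CENTRIC = "target_centric"
    DRUG_CENTRIC = "drug_centric"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class RepositioningCase:
    """One drug with its original and secondary indication and target sets."""

    drug_name: str
    modality: str
    original: Indication
    secondary: Indication
    original_targets: frozenset[TargetProtein] = frozenset()
    secondary_targets: frozenset[TargetProtein] = frozenset()

    def __post_init__(self) -> None:
        if not self.drug_name.strip():
            raise CaseTableError("drug_name must be non-empty")
        if self.modality not in MODALITIES:
            raise CaseTableError(
                f"unknown modality {self.modality!r} for drug {self.drug_name!r}"
            )


def _encode_target(t: TargetProtein) -> str:
    return _FIELD_SEP.join((t.target_id, t.organism, t.molecule_kind))


def _decode_target(token: str, drug_name: str) -> TargetProtein:
    parts = token.split(_FIELD_SEP)
    if len(parts) != 3:
        raise CaseTableError(
            f"malformed target entry {token!r} for drug {drug_name!r}: "
            "expected 'ID|organism|kind'"
        )
    target_id, organism, kind = (p.strip() for p in parts)
    return TargetProtein(
        target_id=target_id.upper(), organism=organism, molecule_kind=kind
    )


def _decode_target_set(cell: str, drug_name: str) -> frozenset[TargetProtein]:
    cell = cell.strip()
    if not cell:
        return frozenset()
    return frozenset(
        _decode_target(tok, drug_name) for tok in cell.split(_TARGET_SEP) if tok.strip()
    )


def read_cases(path: str | Path) -> list[RepositioningCase]:
    """Read a tab-separated case table, preserving row order.

    Raises :class:`CaseTableError` on missing columns or duplicate drug
    names, and propagates :class:`MeshKeyError` for malformed MeSH keys.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in CASE_TABLE_COLUMNS if c not in header]
        if missing:
            raise CaseTableError(
                f"case table {path} is missing mandatory columns: "
                + ", ".join(missing)
            )
        cases: list[RepositioningCase] = []
        seen: set[str] = set()
        for row in reader:
            name = row["drug_name"].strip()
            if name in seen:
                raise CaseTableError(f"duplicate drug name {name!r} in {path}")
            seen.add(name)
            try:
                original = Indication(
                    label=row["original_label"].strip(),
                    mesh_key=parse_mesh_root_key(row["original_mesh"]),
                )
                secondary = Indication(
                    label=row["secondary_label"].strip(),
                    mesh_key=parse_mesh_root_key(row["secondary_mesh"]),
                )
            except MeshKeyError as exc:
                raise CaseTableError(f"drug {name!r}: {exc}") from exc
            cases.append(
                RepositioningCase(
                    drug_name=name,
                    modality=row["modality"].strip(),
                    original=original,
                    secondary=secondary,
                    original_targets=_decode_target_set(
                        row["original_targets"] or "", name
                    ),
                    secondary_targets=_decode_target_set(
                        row["secondary_targets"] or "", name
                    ),
                )
            )
    return cases


def write_cases(cases: Iterable[RepositioningCase], path: str | Path) -> None:
    """Write cases as a tab-separated table (inverse of :func:`read_cases`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CASE_TABLE_COLUMNS)
        for case in cases:
            writer.writerow(
                (
                    case.drug_name,
                    case.modality,
                    case.original.label,
                    case.original.mesh_key.code,
                    case.secondary.label,
                    case.secondary.mesh_key.code,
                    _TARGET_SEP.join(
                        _encode_target(t) for t in sorted(case.original_targets)
                    ),
                    _TARGET_SEP.join(
                        _encode_target(t) for t in sorted(case.secondary_targets)
                    ),
                )
            )


def _validate_sequence(name: str, seq: str) -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in AMINO_ACIDS:
            raise SequenceStoreError(
                f"record {name!r}: illegal residue {ch!r} at position {pos}"
            )
    return seq


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{header token: amino-acid string}``.

    Sequences are upper-cased and restricted to the 20 standard residues
    plus X; duplicate headers are rejected.
    """
    store: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        key = record.id
        if key in store:
            raise SequenceStoreError(f"duplicate FASTA header {key!r} in {path}")
        store[key] = _validate_sequence(key, str(record.seq))
    return store


def write_sequences(store: Mapping[str, str], path: str | Path) -> None:
    """Write a sequence store to FASTA (inverse of :func:`read_sequences`)."""
    records = [
        SeqRecord(Seq(_validate_sequence(k, v)), id=k, description="")
        for k, v in store.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def load_case_fixture() -> list[RepositioningCase]:
    """The packaged 128-case small-molecule/protein-target corpus."""
    with resources.as_file(
        resources.files("repotax.data").joinpath("repositioning_cases.tsv")
    ) as p:
        return read_cases(p)


def load_fixture_sequences() -> dict[str, str]:
    """Toy sequences backing the fixture's cross-organism target pairs."""
    with resources.as_file(
        resources.files("repotax.data").joinpath("ortholog_sequences.fasta")
    ) as p:
        return read_sequences(p)


def case_key_pair(case: RepositioningCase) -> tuple[str, str]:
    """(original, secondary) root-key codes of a case."""
    return case.original.mesh_key.code, case.secondary.mesh_key.code
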