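"""Corpus eligibility filter: small-molecule drugs acting on protein targets.

A case is kept only if the drug is a small molecule and each of its target
sets is compatible with a protein mechanism.  Target sets that mix protein
and non-protein members keep the case but drop the non-protein members; a
non-empty target set with *no* protein member disqualifies the case.  Empty
target sets pass (disease-centric cases never had their targets examined).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core_model import RepositioningCase, TargetProtein

__all__ = ["FilterReport", "RemovedCase", "filter_eligible"]

REASON_MODALITY = "non_small_molecule"
REASON_TARGET = "non_protein_target"


@dataclass(frozen=True)
class RemovedCase:
    case: RepositioningCase
    reason: str


@dataclass
class FilterReport:
    """Outcome of the eligibility filter over one corpus."""

    kept: list[RepositioningCase] = field(default_factory=list)
    removed: list[RemovedCase] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    @property
    def n_input(self) -> int:
        return self.n_kept + self.n_removed

    def to_json_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_removed": self.n_removed,
            "removed": [
                {"drug_name": r.case.drug_name, "reason": r.reason}
                for r in self.removed
            ],
            "kept": [c.drug_name for c in self.kept],
        }


def _protein_subset(targets: frozenset[TargetProtein]) -> frozenset[TargetProtein]:
    return frozenset(t for t in targets if t.molecule_kind == "protein")


def filter_eligible(cases: Iterable[RepositioningCase]) -> FilterReport:
    """Partition cases into kept and removed, with one reason per removal.

    Modality is checked before target kinds, so a non-small-molecule drug
    with non-protein targets is reported as ``non_small_molecule``.
    """
    report = FilterReport()
    for case in cases:
        if case.modality != "small_molecule":
            report.removed.append(RemovedCase(case, REASON_MODALITY))
            continue
        orig_prot = _protein_subset(case.original_targets)
        sec_prot = _protein_subset(case.secondary_targets)
        if (case.original_targets and not orig_prot) or (
            case.secondary_targets and not sec_prot
        ):
            report.removed.append(RemovedCase(case, REASON_TARGET))
            continue
        if orig_prot != case.original_targets or sec_prot != case.secondary_targets:
            case = RepositioningCase(
                drug_name=case.drug_name,
                modality=case.modality,
                original=case.original,
                secondary=case.secondary,
                original_targets=orig_prot,
                secondary_targets=sec_prot,
            )
        report.kept.append(case)
    return report
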