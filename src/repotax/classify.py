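"""Step-wise assignment of repositioning cases to their category.

Rules, evaluated in order with short-circuiting:

1. identical original/secondary root MeSH key  -> disease-centric
   (targets are never examined);
2. a target identifier shared between the two target sets, or an
   original/secondary target pair whose global-alignment identity strictly
   exceeds the configured threshold (an ortholog pair)  -> target-centric;
3. otherwise  -> drug-centric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_model import ClassLabel, RepositioningCase
from .identity import ScoringConfig, ortholog_decision, pair_identity

__all__ = [
    "CaseClassification",
    "ClassificationError",
    "ClassificationSummary",
    "ClassifierConfig",
    "classify_all",
    "classify_case",
    "classify_case_detailed",
    "count_ortholog_cases",
]

RULE_SAME_MESH = "same_mesh_key"
RULE_SHARED_TARGET = "shared_target_id"
RULE_ORTHOLOG = "ortholog_pair"
RULE_RESIDUAL = "residual"


class ClassificationError(ValueError):
    """Raised when one or more cases cannot be classified."""


@dataclass(frozen=True)
class ClassifierConfig:
    identity_threshold: float = 0.30
    target_match_mode: str = "any_shared"  # or "all_shared"
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold < 1.0:
            raise ValueError(
                f"identity_threshold {self.identity_threshold} outside (0, 1)"
            )
        if self.target_match_mode not in ("any_shared", "all_shared"):
            raise ValueError(
                f"unknown target_match_mode {self.target_match_mode!r}"
            )


@dataclass(frozen=True)
class CaseClassification:
    """Label plus the rule that fired (and the matching detail, if any)."""

    label: ClassLabel
    rule: str
    detail: str = ""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ClassificationSummary:
    """Corpus-level label counts, rounded percentages, per-case labels."""

    n_total: int
    n_disease: int
    n_target: int
    n_drug: int
    pct_disease: int
    pct_target: int
    pct_drug: int
    frac_disease: float
    frac_target: float
    frac_drug: float
    per_case: dict[str, ClassLabel]
    per_case_rule: dict[str, str]
    percentages_defined: bool = True

    def to_json_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_disease": self.n_disease,
            "n_target": self.n_target,
            "n_drug": self.n_drug,
            "pct_disease": self.pct_disease,
            "pct_target": self.pct_target,
            "pct_drug": self.pct_drug,
            "frac_disease": self.frac_disease,
            "frac_target": self.frac_target,
            "frac_drug": self.frac_drug,
            "percentages_defined": self.percentages_defined,
            "per_case": {k: v.value for k, v in self.per_case.items()},
            "per_case_rule": dict(self.per_case_rule),
        }


def _ids(targets) -> set[str]:
    return {t.target_id for t in targets}


def _targets_match(case: RepositioningCase, mode: str) -> set[str]:
    orig, sec = _ids(case.original_targets), _ids(case.secondary_targets)
    shared = orig & sec
    if mode == "any_shared":
        return shared
    # all_shared: identical, non-empty identifier sets
    return shared if (orig and orig == sec) else set()


def classify_case_detailed(
    case: RepositioningCase,
    sequences: Mapping[str, str] | None = None,
    cfg: ClassifierConfig | None = None,
) -> CaseClassification:
    """Classify one eligible case, reporting which rule fired.

    Ortholog checking is attempted only for target pairs whose sequences
    are both present in ``sequences``; without sequences only an exact
    identifier match can make a case target-centric.
    """
    cfg = cfg or ClassifierConfig()
    if case.original.mesh_key.code == case.secondary.mesh_key.code:
        return CaseClassification(
            ClassLabel.DISEASE_CENTRIC,
            RULE_SAME_MESH,
            detail=case.original.mesh_key.code,
        )
    if not case.original_targets and not case.secondary_targets:
        raise ClassificationError(
            f"case {case.drug_name!r} has distinct MeSH keys but empty target "
            "sets on both sides; target evidence is required beyond rule 1"
        )
    shared = _targets_match(case, cfg.target_match_mode)
    if shared:
        return CaseClassification(
            ClassLabel.TARGET_CENTRIC,
            RULE_SHARED_TARGET,
            detail=",".join(sorted(shared)),
        )
    if sequences:
        for t_orig in sorted(case.original_targets):
            seq_a = sequences.get(t_orig.sequence_key)
            if seq_a is None:
                continue
            for t_sec in sorted(case.secondary_targets):
                seq_b = sequences.get(t_sec.sequence_key)
                if seq_b is None:
                    continue
                identity = pair_identity(seq_a, seq_b, cfg.scoring)
                if ortholog_decision(identity, cfg.identity_threshold).is_ortholog:
                    return CaseClassification(
                        ClassLabel.TARGET_CENTRIC,
                        RULE_ORTHOLOG,
                        detail=(
                            f"{t_orig.target_id}~{t_sec.target_id}"
                            f" identity={identity:.3f}"
                        ),
                    )
    return CaseClassification(ClassLabel.DRUG_CENTRIC, RULE_RESIDUAL)


def classify_case(
    case: RepositioningCase,
    sequences: Mapping[str, str] | None = None,
    cfg: ClassifierConfig | None = None,
) -> ClassLabel:
    return classify_case_detailed(case, sequences, cfg).label


def classify_all(
    cases: Sequence[RepositioningCase],
    sequences: Mapping[str, str] | None = None,
    cfg: ClassifierConfig | None = None,
) -> ClassificationSummary:
    """Classify a corpus; per-case failures are collected into one error."""
    per_case: dict[str, ClassLabel] = {}
    per_rule: dict[str, str] = {}
    errors: list[str] = []
    for case in cases:
        try:
            c = classify_case_detailed(case, sequences, cfg)
        except ClassificationError as exc:
            errors.append(str(exc))
            continue
        per_case[case.drug_name] = c.label
        per_rule[case.drug_name] = c.rule
    if errors:
        raise ClassificationError(
            f"{len(errors)} case(s) could not be classified:\n" + "\n".join(errors)
        )
    n_total = len(per_case)
    n_disease = sum(1 for v in per_case.values() if v is ClassLabel.DISEASE_CENTRIC)
    n_target = sum(1 for v in per_case.values() if v is ClassLabel.TARGET_CENTRIC)
    n_drug = sum(1 for v in per_case.values() if v is ClassLabel.DRUG_CENTRIC)
    if n_total:
        fracs = (n_disease / n_total, n_target / n_total, n_drug / n_total)
        pcts = tuple(_round_half_up(100.0 * f) for f in fracs)
        defined = True
    else:
        fracs = (0.0, 0.0, 0.0)
        pcts = (0, 0, 0)
        defined = False
    return ClassificationSummary(
        n_total=n_total,
        n_disease=n_disease,
        n_target=n_target,
        n_drug=n_drug,
        pct_disease=pcts[0],
        pct_target=pcts[1],
        pct_drug=pcts[2],
        frac_disease=fracs[0],
        frac_target=fracs[1],
        frac_drug=fracs[2],
        per_case=per_case,
        per_case_rule=per_rule,
        percentages_defined=defined,
    )


def count_ortholog_cases(summary: ClassificationSummary) -> int:
    """Target-centric cases whose rule-2 match was an ortholog pair
    (distinct identifiers/organisms) rather than an identical identifier."""
    return sum(
        1
        for drug, label in summary.per_case.items()
        if label is ClassLabel.TARGET_CENTRIC
        and summary.per_case_rule[drug] == RULE_ORTHOLOG
    )
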