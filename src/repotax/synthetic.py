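"""Synthetic corpora with planted class structure.

Generates case tables whose classifier labels are known by construction:
disease-centric cases share a root key, target-centric cases either share
a target identifier or carry a cross-organism pair of mutated-copy
sequences (identity well above the threshold for moderate mutation
rates), and drug-centric cases get disjoint targets with independent
random sequences (identity far below the threshold at realistic lengths).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import RULE_ORTHOLOG, RULE_SAME_MESH, RULE_SHARED_TARGET
from .core_model import (
    ClassLabel,
    Indication,
    MeshRootKey,
    RepositioningCase,
    TargetProtein,
    mesh_root_key_names,
    parse_mesh_root_key,
)
from .identity import pair_identity

__all__ = [
    "GeneratorConfig",
    "SyntheticCorpus",
    "generate_cases",
    "generate_complex_table",
    "generate_ineligible_cases",
    "largest_remainder_counts",
]

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    n_cases: int = 100
    fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)
    f_ortholog_within_target: float = 0.5
    seq_length: int = 300
    mutation_rate: float = 0.2
    n_mesh_keys: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise GeneratorError("n_cases must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise GeneratorError(
                f"fractions must sum to 1, got {sum(self.fractions)}"
            )
        if any(f < 0 for f in self.fractions):
            raise GeneratorError("fractions must be non-negative")
        if not 0.0 <= self.f_ortholog_within_target <= 1.0:
            raise GeneratorError("f_ortholog_within_target outside [0, 1]")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise GeneratorError("mutation_rate outside [0, 1)")
        if self.seq_length < 1:
            raise GeneratorError("seq_length must be positive")
        if self.n_mesh_keys < 2 and (self.fractions[1] > 0 or self.fractions[2] > 0):
            raise GeneratorError(
                "n_mesh_keys must be >= 2 when target- or drug-centric "
                "fractions are positive"
            )
        if self.n_mesh_keys < 1 or self.n_mesh_keys > len(mesh_root_key_names()):
            raise GeneratorError(
                f"n_mesh_keys must be in [1, {len(mesh_root_key_names())}]"
            )


def largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Apportion ``n`` into integer counts matching ``fractions``.

    Floors first, then distributes the shortfall to the largest fractional
    remainders (ties by position), so counts always sum to ``n``.
    """
    quotas = [n * f for f in fractions]
    counts = [int(q) for q in quotas]
    shortfall = n - sum(counts)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts


@dataclass
class SyntheticCorpus:
    cases: list[RepositioningCase]
    sequences: dict[str, str]
    planted_labels: dict[str, ClassLabel]
    planted_rules: dict[str, str]
    realized_identities: dict[str, float] = field(default_factory=dict)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_RESIDUES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i, ch in enumerate(out):
        if rng.random() < rate:
            alt = rng.choice(_RESIDUES)
            while alt == ch:
                alt = rng.choice(_RESIDUES)
            out[i] = str(alt)
    return "".join(out)


def _pick_distinct_keys(
    rng: np.random.Generator, pool: list[MeshRootKey]
) -> tuple[MeshRootKey, MeshRootKey]:
    i, j = rng.choice(len(pool), size=2, replace=False)
    return pool[int(i)], pool[int(j)]


def generate_cases(cfg: GeneratorConfig) -> SyntheticCorpus:
    """Generate a case table with planted labels; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    key_pool = [
        parse_mesh_root_key(code)
        for code in sorted(mesh_root_key_names())[: cfg.n_mesh_keys]
    ]
    n_disease, n_target, n_drug = largest_remainder_counts(
        cfg.n_cases, cfg.fractions
    )
    corpus = SyntheticCorpus(
        cases=[], sequences={}, planted_labels={}, planted_rules={}
    )
    target_serial = 0

    def next_target_id() -> str:
        nonlocal target_serial
        target_serial += 1
        return f"T{target_serial:05d}"

    def indication(key: MeshRootKey) -> Indication:
        return Indication(label=key.name or key.code, mesh_key=key)

    schedule = (
        [(ClassLabel.DISEASE_CENTRIC, RULE_SAME_MESH)] * n_disease
        + [(ClassLabel.TARGET_CENTRIC, RULE_SHARED_TARGET)] * n_target
        + [(ClassLabel.DRUG_CENTRIC, "residual")] * n_drug
    )
    for serial, (label, rule) in enumerate(schedule, start=1):
        drug = f"DRUG{serial:05d}"
        if label is ClassLabel.DISEASE_CENTRIC:
            key = key_pool[int(rng.integers(len(key_pool)))]
            case = RepositioningCase(
                drug_name=drug,
                modality="small_molecule",
                original=indication(key),
                secondary=indication(key),
            )
        elif label is ClassLabel.TARGET_CENTRIC:
            k1, k2 = _pick_distinct_keys(rng, key_pool)
            if rng.random() < cfg.f_ortholog_within_target:
                rule = RULE_ORTHOLOG
                id_a, id_b = next_target_id(), next_target_id()
                seq_a = _random_protein(rng, cfg.seq_length)
                seq_b = _mutate(rng, seq_a, cfg.mutation_rate)
                corpus.sequences[id_a] = seq_a
                corpus.sequences[id_b] = seq_b
                corpus.realized_identities[drug] = pair_identity(seq_a, seq_b)
                orig = frozenset({TargetProtein(id_a, organism="organism A")})
                sec = frozenset({TargetProtein(id_b, organism="organism B")})
            else:
                rule = RULE_SHARED_TARGET
                tid = next_target_id()
                orig = frozenset({TargetProtein(tid, organism="organism A")})
                sec = frozenset({TargetProtein(tid, organism="organism A")})
            case = RepositioningCase(
                drug_name=drug,
                modality="small_molecule",
                original=indication(k1),
                secondary=indication(k2),
                original_targets=orig,
                secondary_targets=sec,
            )
        else:
            k1, k2 = _pick_distinct_keys(rng, key_pool)
            id_a, id_b = next_target_id(), next_target_id()
            corpus.sequences[id_a] = _random_protein(rng, cfg.seq_length)
            corpus.sequences[id_b] = _random_protein(rng, cfg.seq_length)
            corpus.realized_identities[drug] = pair_identity(
                corpus.sequences[id_a], corpus.sequences[id_b]
            )
            case = RepositioningCase(
                drug_name=drug,
                modality="small_molecule",
                original=indication(k1),
                secondary=indication(k2),
                original_targets=frozenset(
                    {TargetProtein(id_a, organism="organism A")}
                ),
                secondary_targets=frozenset(
                    {TargetProtein(id_b, organism="organism B")}
                ),
            )
        corpus.cases.append(case)
        corpus.planted_labels[drug] = label
        corpus.planted_rules[drug] = rule
    return corpus


def generate_ineligible_cases(
    n: int, seed: int = 0, start_serial: int = 1
) -> list[RepositioningCase]:
    """Cases violating the small-molecule/protein-target scheme.

    Cycles through the violation modes: antibody drugs, therapeutic
    proteins, small molecules with nucleic-acid targets, and small
    molecules with targets of unknown kind.
    """
    rng = np.random.default_rng(seed)
    key_pool = [parse_mesh_root_key(code) for code in sorted(mesh_root_key_names())]
    cases = []
    for i in range(n):
        key_a = key_pool[int(rng.integers(len(key_pool)))]
        key_b = key_pool[int(rng.integers(len(key_pool)))]
        drug = f"BAD{start_serial + i:05d}"
        mode = i % 4
        if mode == 0:
            modality, kind = "antibody", "protein"
        elif mode == 1:
            modality, kind = "protein", "protein"
        elif mode == 2:
            modality, kind = "small_molecule", "nucleic_acid"
        else:
            modality, kind = "small_molecule", "unknown"
        targets = frozenset(
            {TargetProtein(f"BT{start_serial + i:05d}", molecule_kind=kind)}
        )
        cases.append(
            RepositioningCase(
                drug_name=drug,
                modality=modality,
                original=Indication(label=key_a.name or key_a.code, mesh_key=key_a),
                secondary=Indication(label=key_b.name or key_b.code, mesh_key=key_b),
                original_targets=targets,
                secondary_targets=targets,
            )
        )
    return cases


def generate_complex_table(
    cases: Sequence[RepositioningCase], coverage_prob: float, seed: int = 0
) -> list[tuple[str, str, str]]:
    """Independent per-(drug, target) inclusion with ``coverage_prob``."""
    if not 0.0 <= coverage_prob <= 1.0:
        raise GeneratorError("coverage_prob outside [0, 1]")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str]] = []
    serial = 0
    for case in cases:
        pairs = sorted(
            {
                (case.drug_name, t.target_id)
                for t in case.original_targets | case.secondary_targets
            }
        )
        for drug, target in pairs:
            if rng.random() < coverage_prob:
                serial += 1
                rows.append((drug, target, f"PDB{serial:04d}"))
    return rows
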