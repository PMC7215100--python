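# repotax

Taxonomy and network analysis of drug-target-indication repositioning
cases. Given a table of repositioning events (drug, original and secondary
indication with top-level MeSH disease-category keys, and the protein
target sets on each side), the package:

1. **filters** the corpus to small-molecule drugs acting on protein
   targets (`repotax.eligibility`);
2. **classifies** each case step-wise (`repotax.classify`):
   *disease-centric* when both indications share a root MeSH key,
   *target-centric* when the target sets share an identifier or a
   cross-organism pair aligns with >30% sequence identity, and
   *drug-centric* otherwise;
3. **aligns** protein pairs with an exact Needleman-Wunsch global aligner
   (linear gaps, BLOSUM62) and scores identity as
   (identical + similar residues) / alignment length
   (`repotax.identity`);
4. **builds** an undirected typed graph per class (drug, target, and
   indication nodes) and summarizes it: component shares, per-type
   clustering, transitivity, interpolated 90th-percentile effective
   diameter, and the small-world score
   `transitivity * n_nodes / effective_diameter` (`repotax.network`);
5. **reports** the original-by-secondary indication contingency matrix,
   per-category tallies, and structural coverage against a local
   drug-target complex snapshot (`repotax.reporting`);
6. **simulates** corpora with planted class fractions and ortholog
   sequence pairs of controlled identity for testing
   (`repotax.synthetic`).

A 128-case reference corpus and the toy sequences backing its five
cross-organism target pairs ship as packaged data
(`repotax.load_case_fixture()` / `repotax.load_fixture_sequences()`).

## CLI

```bash
# classify a case table (TSV; see repotax/data/repositioning_cases.tsv)
repotax classify --cases cases.tsv --fasta seqs.fasta --out summary.json

# pairwise identity + ortholog decisions for a 2-column pair list
repotax identity --fasta seqs.fasta --pairs pairs.tsv --out identity.tsv

# per-class graph summary and optional typed edge list
repotax network --cases cases.tsv --class drug_centric --out net.json \
    --edgelist edges.tsv

# contingency matrix, tallies, and optional structural coverage
repotax report --cases cases.tsv --complexes pdb_snapshot.tsv --out-dir reports/

# synthetic corpus with planted labels
repotax simulate --config gen.yaml --out-dir sim/
```

Classifier options (`--config` YAML): `identity_threshold` (default 0.30),
`target_match_mode` (`any_shared`/`all_shared`), `matrix_name`,
`gap_penalty`.

## File formats

- **Case table** (TSV): columns `drug_name`, `modality`, `original_label`,
  `original_mesh`, `secondary_label`, `secondary_mesh`,
  `original_targets`, `secondary_targets`; target sets are
  semicolon-separated `ID|organism|kind` triples; MeSH keys may be full
  tree numbers (truncated to the root at ingest).
- **Sequences**: plain FASTA, standard residues plus X.
- **Complex table** (TSV): `drug_name`, `target_id`, `structure_id`.
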