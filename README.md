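# lta — Lipid Traffic Analysis

A tested, reusable pipeline for analysing how lipid metabolism differs
between two phenotypes across a network of connected tissue compartments.
Given per-sample lipidomics abundances (long-format delimited text) and a
compartment network, it:

* **Switch Analysis** — calls each lipid *present* in a group when its
  signal exceeds zero in ≥ 66 % of the group's samples (integer-arithmetic
  rule, so 2-of-3 passes), then classifies every lipid per scope:
  **A-type** (present in both phenotypes), **B-type** (present in exactly
  one, attributed to it) at every compartment and every network axis, and
  **U-type** (present in every compartment of the network for a phenotype).
* **Jaccard-Tanimoto comparison** — per scope, the similarity *J* of the
  two phenotypes' presence lists with a margin-preserving permutation
  p-value (seeded, reproducible; p is never reported below 1/(B+1)).
* **Abundance Analysis** — error-normalised fold change (ENFC) between
  phenotypes per compartment at head-group class level and for species
  subpanels (DNL-marker TGs, PUFA-containing species, or explicit lists).
  ENFC here is the log2 fold change divided by its delta-method standard
  error; positive means higher in the non-reference group. Whether the
  original tool used log2 or natural log is not published; the definition
  is documented in `lta.abundance_analysis` and substitutable.
* **Synthetic data** — a generator that plants known switch patterns and
  abundance effects into a two-phenotype multi-compartment design and
  emits both the dataset and a machine-readable ground truth, so the whole
  analysis is verifiable at desk scale.

Lipid names use sum-composition shorthand `HEAD(C:D)`, e.g. `TG(52:7)`,
`PI(38:6)`; grouped lists like `PI(36:2, 36:3)` are supported by the
nomenclature helpers.

## CLI

Generate the bundled synthetic fixture and analyse it:

```sh
lta simulate --design paper-fixture --out sim/ --seed 11
lta run --data sim/abundances.tsv --out results/ --reference control \
        --threshold 66 --permutations 10000 --seed 4
```

`lta run` writes `presence.tsv`, `switch_types.tsv`, `switch_jaccard.tsv`,
`enfc_class.tsv`, per-panel ENFC tables and a `run_summary.json` capturing
config, seed, thresholds and version. Identical config + seed gives
byte-identical outputs. `--network` accepts a YAML file with
`compartments:` and `axes:`; the default is an 8-compartment star with
serum as the hub (serum–liver, serum–brain, serum–heart atria,
serum–heart ventricles, serum–spleen, serum–renal medulla,
serum–renal cortex). A YAML config may replace flags (`--config`);
flags win on conflict.

`lta simulate --design <file>` accepts a YAML design (network, lipid
panel, planted switches/ubiquitous lipids/absences/effects, dropout);
`paper-fixture` is a bundled design whose planted pattern mirrors the
qualitative findings the pipeline should recover.

## Input format

Comma- or tab-delimited UTF-8 text with header columns exactly
`sample_id, phenotype, compartment, lipid, signal`. Exactly two phenotype
labels; signals non-negative; a missing (sample, compartment, lipid)
record means signal 0.

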