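# promsets

Construction of structured **multi-target (MT) / single-target (ST)
compound datasets** from biological screening data, as a tested, reusable
pipeline:

1. **Assay curation** — an ordered filtering cascade (assay source, target
   mapping, organism, antitargets, hit rate > 2 %, reported
   inconsistencies/cytotoxic readouts, assay format) with a per-rule
   attrition report, plus detection of assays carrying conflicting
   compound–target annotations.
2. **Compound screening** — interference filters (PAINS-style substructure
   patterns, empirical liability rules, aggregator and firefly-luciferase
   inhibitor deny-lists).
3. **Promiscuity grouping** — a ternary compound × target activity matrix,
   per-compound promiscuity degree (PD = number of active targets) and test
   frequency, MT selection at a PD threshold (≥ 5, with ≥ 3 as a control),
   and assembly of *experimentally complete* compound groups: each MT
   compound is paired, per active target, with an ST compound (PD = 1)
   confirmed inactive against the group's remaining targets; each ST
   compound is used at most once.
4. **Set reduction** — the two reduced halves: random removal of 50 % of
   groups, and iterative nearest-neighbor removal (25 % by maximum ST–ST
   fingerprint similarity, then 25 % by MT–MT similarity).
5. **Prediction benchmark** — MT-vs-ST classification (RBF-SVM, 1-NN with
   Tanimoto distance, random forest) on Morgan fingerprints over repeated
   balanced trials, scored by balanced accuracy, contrasting the original
   dataset against its randomly and NN-reduced variants.
6. **Synthetic worlds** — a generator of complete screening worlds (real
   enumerable scaffold/substituent structures, assays, binary outcomes)
   with planted ground truth for every pipeline stage, backing the test
   suite.

Datasets are read and written in a tab-delimited dialect with the seven
columns `NostereoAromaticSMILES`, `is_MT`, `group`, `cid`, `target_ids`,
`n_tested`, `random_removal_set`, `nn_removal_set`.

## Command line

```sh
promsets simulate --seed 3 --out world/            # synthetic world
promsets curate --assays world/assays.tsv --records world/records.tsv \
                --report attrition.tsv             # assay cascade report
promsets group --matrix matrix.tsv --pd-min 5 --out dataset.tsv
promsets verify --tsv dataset.tsv                  # invariants + summary
promsets summary --tsv dataset.tsv --json summary.json
promsets reduce --tsv dataset.tsv --method both --seed 7 --out marked.tsv
promsets benchmark --tsv dataset.tsv --trials 10 --seed 7 --json bench.json
```

## Layout

| path                                   | contents                                  |
|----------------------------------------|-------------------------------------------|
| `src/promsets/activity_data.py`        | record/group/dataset model, TSV dialect IO |
| `src/promsets/chem.py`                 | canonical SMILES, Morgan fingerprints, Tanimoto |
| `src/promsets/assay_curation.py`       | filtering cascade, inconsistency detector |
| `src/promsets/compound_screening.py`   | liability rule sets and record removal    |
| `src/promsets/promiscuity_grouping.py` | activity matrix, PD, group assembly       |
| `src/promsets/set_reduction.py`        | random / nearest-neighbor reduction       |
| `src/promsets/prediction_benchmark.py` | MT-vs-ST classification benchmark         |
| `src/promsets/synthetic_data.py`       | synthetic worlds with planted ground truth |
| `src/promsets/cli.py`                  | `promsets` console entry point            |
| `tests/`                               | unit, property and acceptance suites      |
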