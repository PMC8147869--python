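# Deposited dataset files (not redistributed)

The deposition-verification acceptance targets (t1–t6) and the
`TestCriterion1DepositionVerification` tests compare the package's dataset
reader against the three published screening-compound dataset files from
the open-access Zenodo deposition that accompanies the source data note.

Those files are not redistributed here. To enable verification, download
the deposition and place its three tab-delimited files in this directory
under the following names:

| file                  | contents                                |
|-----------------------|-----------------------------------------|
| `mixed_pd5.tsv`       | mixed assay set, PD ≥ 5                 |
| `biochemical_pd5.tsv` | biochemical assay set, PD ≥ 5           |
| `biochemical_pd3.tsv` | biochemical assay set, PD ≥ 3           |

Each file must carry the seven deposited columns
(`NostereoAromaticSMILES`, `is_MT`, `group`, `cid`, `target_ids`,
`n_tested`, `random_removal_set`, `nn_removal_set`).

With the files in place:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
promsets verify --tsv data/deposited/biochemical_pd5.tsv
```

Without them, the acceptance script omits t1–t6 and the criterion-1 tests
fail with a message pointing here.
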