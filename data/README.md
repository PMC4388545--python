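# Reference dataset slot

The per-eye cohort spreadsheet deposited with the original study is not
redistributed here. To run the published-statistics reproduction check
(`tests/test_acceptance.py::test_reference_cohort_statistics_reproduced`)
and analyze the real cohort, place the files in this directory:

- `s1_dataset.xlsx` (or `s1_dataset.csv`) — the deposited per-eye table;
- `s1_columns.yaml` (optional) — a mapping from canonical column names to
  the spreadsheet's headers, e.g.:

```yaml
amplitude_rater1: "Amplitude rater 1 (pixels)"
amplitude_rater2: "Amplitude rater 2 (pixels)"
ovality_ratio: "Ovality ratio"
spherical_equivalent: "Spherical equivalent (D)"
axial_length: "Axial length (mm)"
body_height: "Height (cm)"
```

Canonical names are listed in `disctilt.cohort.CANONICAL_COLUMNS`. The
same mapping works on the command line via
`disctilt --config map.yaml cohort data/s1_dataset.xlsx` with the mapping
under a top-level `columns:` key.
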