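# Published KASP-panel fixtures (not distributed)

This directory is the documented drop-in location for the published
phenotype and marker-panel tables of the 'Baleng Crab' × 'M9' apple
rootstock study, which are **not redistributed** with this package.
Tests that reproduce the published panel numbers look for the following
plain-text TSV files here and fail with an explanatory message when they
are absent:

- `gap_table_SID.tsv`, `gap_table_AID.tsv`, `gap_table_SAID.tsv` —
  one row per genotyped hybrid: a `hybrid_id` column, one column per
  KASP marker (e.g. `SH14275`) holding genotype call strings, an
  optional `GPV` column (ignored for fitting) and an `OPV` column with
  the observed injury index.
- `phenotypes.tsv` — tidy injury-index records with columns
  `hybrid_id`, `year`, `trait` (SID/AID/SAID), `value` in [0, 1].

To assemble them, export the corresponding supplementary worksheets of
the study to TSV with the column names above.
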