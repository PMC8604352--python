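# Published reference data (user-supplied)

This directory is the documented drop-in location for transcriptions of the
published reference artifacts, which are distributed as spreadsheet
supplements alongside the original article and are **not redistributed
here**:

- `pssm.tsv` — the published combined 5x20 PSSM ("Paladin 5x20 PSSM"
  supplementary table), exported to TSV in the package's PSSM layout: a
  `site` column with rows `-2, -1, 0, +1, +2`, then one column per residue
  (the 20 standard amino acids, one-letter code), values in kcal/mol.
- `benchmark.tsv` — the structure benchmark (available chaperone-substrate
  complex structures), columns `sequence`, `orientation`
  (`forward`/`reverse`), `core` (the observed five-residue binding core),
  `offset` (0-based offset of the core in the sequence), `structure_id`.

To create them, open the published supplementary spreadsheets, export each
sheet to TSV, and arrange the columns as above.
`paladin.datasets.load_published_pssm()` and
`paladin.datasets.load_structure_benchmark()` read these files and raise a
clear error when they are absent.  All tests and examples that reproduce the
published worked-example scores and benchmark counts require them.
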