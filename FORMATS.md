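# On-disk formats

All tables are tab-delimited UTF-8 with a header row; missing values are
written as `NA`. These dialects are produced by `phosig.io` writers and by the
synthetic cohort generator, and are the only formats the readers accept.

## Site table (`site_table.tsv`)

One row per phospho-site. Columns, in order:

| column       | type    | notes |
|--------------|---------|-------|
| `site_id`    | string  | canonical form `PROTEIN_pRESIDUEPOSITION`, e.g. `RBMX_pS326`; unique |
| `protein_id` | string  | |
| `gene_symbol`| string  | |
| `position`   | int     | 1-based residue position on the protein |
| `residue`    | S/T/Y   | the phospho-acceptor |
| `window_13`  | string  | 13 characters, acceptor at index 7 (1-based); termini padded with `_` |
| `loc_prob`   | float   | localization probability in [0, 1] |
| *sample columns* | float | raw (linear-scale) reporter intensity per sample, `NA` when missing; reference channels included |

Validation: window length exactly 13 and centre equal to `residue`;
`position >= 1`; duplicate `site_id` rejected.

## Sample sheet (`sample_sheet.tsv`)

One row per TMT channel (patients and references). Required columns, in order:

| column | values |
|--------|--------|
| `sample_id` | unique |
| `plex_id` | e.g. `plex1` |
| `channel_id` | unique within plex |
| `is_reference` | 0/1 — exactly one reference per plex |
| `regimen` | `DA` or `DAV` (`NA` for references) |
| `response` | `CR` or `NR` (`NA` for references) |

Optional clinical columns: `age`, `sex` (M/F), `wbc`, `n_count`, `hgb`,
`plt`, `bm_blasts`, `karyotype_risk`, `eln_risk`. The four analysis groups
are `regimen-response` combinations (`DA-CR`, `DA-NR`, `DAV-CR`, `DAV-NR`).

## Kinase–substrate map (`kinase_substrate_map.tsv`)

| column | notes |
|--------|-------|
| `kinase_id` | |
| `substrate_protein_id` | |
| `position` | 1-based |
| `residue` | S/T/Y |

Duplicate (kinase, protein, position) triples are dropped with a logged
warning. Readers derive a `site_id` column in the canonical form for joining
against site tables.

## Ground truth (`ground_truth.json`)

JSON object with keys `true_active_kinases` (list of
`[kinase_id, contrast_id, delta]`), `true_differential_sites`
(contrast → site_id → `up`/`down`), `planted_motif` (13-char rendering or
null) and `censoring_threshold` (log2 intensity or null). Contrast ids are
`TEST_vs_REF` group labels, e.g. `DA-NR_vs_DA-CR`.

## Results directory

`phosig run-all` writes one `.tsv` per result table, one `.json` per
structured object, and `manifest.json` mapping each file name to its sha256
hash. Deterministic stages reproduce identical hashes for a fixed config and
seed.
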