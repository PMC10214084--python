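# External inputs (not distributable, not downloadable offline)

Some acceptance checks need third-party data that this repository cannot
ship and that cannot be fetched in an offline environment.  Place the
files below in this directory to enable them.

| File | Content | Enables |
|------|---------|---------|
| `P36873.fasta` | UniProt P36873 (human PP1 catalytic subunit, gamma) | insert detection (t8/t9) |
| `Q9FN02.fasta` | UniProt Q9FN02 (Arabidopsis PP7) | insert detection (t8/t9) |
| `table_s1.tsv` | Transcription of the published supplementary interaction table; columns: `regulator`, `residue_position` (catalytic-subunit author numbering), optional `residue_name` — one row per recorded residue interaction | census aggregation (t2/t3) |
| `census_manifest.tsv` | Columns: `structure` (file name in this directory), `cat_chain`, `partner_chain`, `regulator`, `offset` (author-numbering offset vs the catalog reference) | structure census (t5/t6, and t2/t3 as fallback) |
| `2O8A.pdb`, `3P71.pdb`, `5J28.pdb`, ... | Deposited co-structure coordinate files referenced by the manifest | structure census |

Sequences: `https://rest.uniprot.org/uniprotkb/<ACC>.fasta`.
Structures: `https://files.rcsb.org/download/<ID>.pdb`.
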