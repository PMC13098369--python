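# File formats

All tabular files are tab-separated UTF-8. Lines starting with `#` are
comments and ignored. Missing values are errors (no sentinel such as `.` is
recognized), so malformed inputs fail fast.

## Expression matrix (`expression.tsv`)

First column `gene` (unique ids), one column per sample. Sample headers are
`genotype_condition_replicate`, e.g. `OE_drought_3`. Values are log-scale
expression.

## Annotation (`annotation.tsv`)

Two columns, no header: gene id, class. Class is `TF` or `structural`;
anything else is rejected.

## Differential-expression table (`*.tsv`)

Columns: `gene`, `log2fc`, `pvalue`, `fdr` (Benjamini–Hochberg adjusted).
The DEG output adds `direction` ∈ {`up`, `down`}.

## Coexpression pair list

Columns: `gene_x`, `gene_y`, `r`, `p`, `n` with `gene_x < gene_y`
lexicographically.

## Network edge list (`edges.tsv`) and summary (`summary.json`)

Edge columns: `regulator`, `target`, `regulator_layer`, `target_layer`,
`min_pcc` (smallest |PCC| among the supporting pairs). Orphan edges —
mediation calls that do not fit the consecutive-layer template — are
written to a separate file with the same columns (layers blank when
unassigned). The JSON summary has `layer_sizes` (layers 1–4),
`edge_counts` (interlayer strata 1–2, 2–3, 3–4) and `total` = their sum.

## Ground-truth network (`truth_edges.tsv`, `truth_layers.json`)

Two-column edge list `regulator`, `target`; the JSON sidecar records
`root_tf`, `layer2`, `layer3`, `layer4` and the generator `seed`.

## Verification table (`verification.tsv`)

Columns: `regulator`, `target`, `layer_pair` (`1-2`/`2-3`/`3-4`),
`chip_fragments` (comma-separated fragment indices 1–4, or `-` for none),
`qpcr_fold`, `qpcr_p`. The summary JSON reports, per layer pair: `n`,
`n_direct`, `n_indirect`, `n_unconfirmed`, `pct_direct`, `pct_indirect`,
`pct_overall` (percentages rounded to the nearest integer, half away from
zero).

## Promoters (`promoters.fasta`)

FASTA; record id = gene id. The description carries the ground-truth
insertion log as `planted=ELEMENT:STRAND:START;...` (START is the 1-based
plus-strand position of the full inserted site), plus `gc=` and `seed=`.

## Motif hit table

Columns: `seq_id`, `fragment_index`, `element`, `label` (`p+`/`p-`),
`strand`, `offset` (1-based start on the + strand, local to the scanned
sequence), `matched` (bases as read 5'→3' on the hit strand).

## Coordinates

Promoter positions are 1-based inclusive. The upstream axis runs
`-region_length..-1` with `-1` abutting the transcription start;
`pcgrn.io.upstream_to_sequence_pos` / `sequence_to_upstream_pos` convert.

## Run configuration (`config.json`)

JSON object with any of the `pcgrn.RunConfig` fields: `cc_min`, `cc_p_max`,
`pcc_max`, `deg_fdr_max`, `deg_min_fold`, `reg_min_fold`, `reg_p_max`,
`root_tf`, `n_fragments`, `region_length`, `strands`, `pcc_formula`,
`signed_cc`, `seed`. Unknown keys are rejected.
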