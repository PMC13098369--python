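# pcgrn

TF-centered hierarchical gene-regulatory-network (GRN) inference from
expression data via first-order partial correlation, with the surrounding
pipeline a drought-stress transcriptomics study needs: DEG filtering,
wet-lab verification scoring, promoter cis-element scanning, and a
planted-network simulator that gives every stage a recoverable ground
truth.

## The problem and the method

A single stress-responsive transcription factor (a bZIP in birch, in the
motivating system) is perturbed — overexpression (OE), knockdown (RE) and
wild type (WT) — under control and drought conditions, and the question is
which genes it regulates, directly and through intermediate TFs. The
network is built in four layers: the root TF, second- and third-layer TFs,
and fourth-layer structural genes.

Inference proceeds in three steps across samples of a genes × samples
expression matrix:

1. **Coexpression.** A gene pair (x, y) is coexpressed when the Pearson
   correlation passes |CC| ≥ 0.8 with p < 0.001 (two-sided t test on
   n − 2 df).
2. **Mediation.** For each coexpressed pair and each candidate TF z not in
   the pair, the first-order partial correlation

   r_xy|z = (r_xy − r_xz·r_yz) / (√(1 − r_xz²)·√(1 − r_yz²))

   is computed. |r_xy|z| < 0.3 means z statistically explains the pair's
   coexpression, and directed edges z→x and z→y are recorded (deduplicated,
   with all supporting pairs kept per edge).
3. **Layer assembly.** Breadth-first search from the root TF assigns
   layers: TFs with a retained root edge form layer 2, TFs first reached
   from layer 2 form layer 3, structural genes first reached from layer 3
   form layer 4. Edges that do not connect consecutive layers are kept
   aside as orphans, never silently dropped.

The DEG gate (FDR < 0.05, absolute fold change ≥ 2), the verification
arithmetic (ChIP-PCR on four 500 bp promoter fragments → *direct*;
qPCR fold ≥ 2 with p < 0.05 and no binding → *indirect*; else
*unconfirmed*), 2^−ΔΔCt quantification, and the three promoter elements
bound by the root TF (GATA-box ATGATAAGG; TGGT-box, core [C/T]GGT;
GGAT-box, core GGAT) are implemented alongside.

## Worked example

```python
from pcgrn import GRNModel, SimulationDesign, generate_grn_topology

net = generate_grn_topology(n2=5, n3=8, n4=20, seed=42)   # planted truth
model = GRNModel.from_simulation(net, SimulationDesign(seed=42))
res = model.fit()
print(res.summary())
```

prints

```
Hierarchical GRN inference results
==================================================
Root TF:              TF001
Samples:              60
Genes in matrix:      34
Thresholds:           |CC| >= 0.8, p < 0.001, |PCC| < 0.3
Coexpressed pairs:    79
Mediation edges:      39
--------------------------------------------------
Layer sizes (1..4):   [1, 3, 5, 10]
Interlayer edges:     [3, 5, 10]
Total relationships:  18
Orphan edges:         21
--------------------------------------------------
Edge precision:       1.000
Edge recall:          0.545
Layer accuracy:       0.559
```

Reading it: from a simulated 3-genotype × 2-condition × 10-replicate
design (60 samples) over 34 genes, 79 pairs pass the coexpression gate and
the mediation scan yields 39 directed edges, of which 18 fit the
consecutive-layer template. Every retained edge is a planted edge
(precision 1.0) while about half the planted edges are recovered at this
operating point — the trade-off the thresholds buy on data this small; see
`docs/methods.md` for the calibration analysis and the method's operating
window.

The same pipeline runs from the shell on TSV/FASTA inputs:

```bash
pcgrn simulate --seed 42 --outdir sim/
pcgrn grn --expression sim/expression.tsv --annotation sim/annotation.tsv \
          --root-tf TF001 --outdir grn/
pcgrn scan --promoters sim/promoters.fasta --out hits.tsv
pcgrn verify --table sim/verification.tsv --out verify.json
```

File layouts are documented in `FORMATS.md`.

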