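# pool3seq

Simulation and analysis toolkit for **pooled, dual-indexed 3'-end RNA-seq**
(3'-tag sequencing of bulk RNA in plates).

## The problem

3'-tag protocols sequence a single 3'-terminal fragment per transcript:
samples are barcoded during reverse transcription with an oligo-dT-anchored
i7 index (6 nt, the *sample* index), pooled early — e.g. all twelve wells of
a plate row into one pool — and each pool is barcoded with an i5 index
(8 nt, the *pool* index) during the final amplification.  A full 96-well
plate therefore needs only 8 + 12 indices.  The price of early pooling is a
pair of technical confounds:

* **column effects** — per-i7-primer efficiency differences applied before
  pooling (a per-sample scale factor, removed by normalisation), and
* **row effects** — anything that happens to a pool after mixing perturbs
  the *composition* of all its samples coherently and survives
  normalisation.

Because an identical ERCC spike-in mix goes into every well, spike-in
profiles should be exchangeable across samples; PCA of the samples × species
log-abundance matrix, with the coefficient of determination
R² = SS_between/SS_total of PC1 scores grouped by plate row (or column),
diagnoses pooling effects, and the pool id then enters the differential
expression model as a categorical covariate.

`pool3seq` implements the whole desk-scale workflow:

| module | contents |
|---|---|
| `core_io` | barcodes, plate layouts, sample sheets, FASTQ (`i7+i5` header comments), a transcript-space GTF dialect, ERCC tables |
| `simulate` | synthetic transcriptomes and full sequencing runs: 3'-terminal fragments (mean molecule 550 bp = insert + 136 bp adapters), 70 nt reads, polyA read-through, column/row bias injection, negative-binomial counting noise, truth tables |
| `preprocess` | dual-index demultiplexing (per-index Hamming matching) and positional polyA trimming (runs ≥ 12 nt starting after read position 25) |
| `quantify` | seed-and-extend transcriptome alignment (mismatch fraction ≤ 0.1), strand-aware unique-read counting, **length-free TPM** (counts scaled to 10⁶, no gene-length division — each transcript contributes one fragment), QC metrics, gene-body 3'-bias profiles, down-sampling detection curves |
| `qc_spikein` | ERCC accuracy (Pearson r of log2 observed vs known concentration), sample-pair correlations, pooling-effect PCA with permutation tests |
| `diffexp` | NB-GLM differential expression: median-of-ratios size factors, moment dispersions shrunk to a trend, vectorised IRLS, Wald tests, BH FDR, DEG calls at q < 0.05 and \|log2FC\| > 1, ROC/AUC against a truth set |

## Worked example

Simulate a 12-sample run (two row pools × six columns, vehicle/treated
interleaved within rows), process it end to end, and ask whether pooling
distorted the plate:

```python
import numpy as np, pandas as pd
from pool3seq import core_io, simulate, preprocess, quantify, qc_spikein, diffexp

layout = core_io.make_row_pooling_layout(2, 6, conditions=["vehicle", "treated"] * 6)
reference = simulate.build_reference(n_mrna=500, seed=1)
fc = {"treated": {"GENE00007": 2.5, "GENE00019": -2.0}}   # two true DEGs
profile = simulate.simulate_expression(layout, reference, fc_spec=fc, depth=50_000, seed=1)
reads, truth = simulate.simulate_reads(profile, reference, seed=1)

demux = preprocess.demultiplex(reads, layout, max_mismatch=1)

index = quantify.TranscriptomeIndex(reference.fasta_sequences())
alignments, lengths = {}, {}
for sample, rs in demux.assigned.items():
    trimmed, _ = preprocess.trim_reads(rs)
    alignments[sample] = quantify.align_reads(trimmed, index)
    lengths.update({r.read_id: len(r.sequence) for r in trimmed})
cm = quantify.assign_and_count(alignments, reference.annotations(), read_lengths=lengths)

ercc_tpm = cm.tpm.loc[cm.tpm.index.isin(reference.ercc.ids)]
pca = qc_spikein.pooling_effect_pca(np.log2(ercc_tpm + 1).T, layout, seed=0)

conditions = pd.Series(layout.condition_of())
pools = pd.Series(layout.pool_of())
res = diffexp.run_de(cm.counts.loc[reference.ids_of_class("mRNA")],
                     conditions, pools=pools, baseline="vehicle")
```

Output (printed by the statements above plus a few summaries):

```
simulated 633038 reads for 12 samples
demultiplexed: 633019 assigned, 19 no-match, 0 ambiguous
mean spike-in accuracy r = 0.879
pooling check: R2_row = 0.96 (p = 0.0040), R2_col = 0.02 (p = 0.9580)
           baseMean  log2FC  pvalue  qvalue    DEG
GENE00007   52.6084  2.1073  0.0000  0.0042   True
GENE00019    5.2438 -1.6488  0.0097  0.6912  False
DEGs with pool covariate: 1
DEGs without covariate:   0
```

Reading the numbers: demultiplexing loses only reads whose indices were hit
by sequencing errors beyond the 1-mismatch budget, and is never ambiguous
because the bundled index pools keep pairwise Hamming distance ≥ 3.  The
spike-in PCA flags a strong row (pool) effect — the simulator injected one —
while columns look clean, mirroring how a real plate experiment is triaged.
With the pool covariate in the design the up-regulated gene is recovered at
q < 0.05; without it, nothing survives FDR control.  The down-regulated gene
is expressed too low (baseMean ≈ 5) to reach significance at this depth — a
power limit, not an error.

The same workflow is available from the shell: `pool3seq simulate`, `demux`,
`trim`, `quant`, `saturation`, `ercc-qc`, `plate-check`, `de`, `roc`
(see `pool3seq --help`).

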