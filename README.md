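# pras — Protein-RNA Association Strength

`pras` ranks candidate functional mRNA targets of an RNA-binding protein
(RBP) from CLIP-seq data. Peak callers tell you *where* an RBP binds;
they do not tell you *which* of the thousands of bound mRNAs the protein
actually regulates. For RBPs that act through a positional mechanism —
stability regulators binding near the polyadenylation site, for example —
both the strength of binding and its position on the transcript are
informative. `pras` combines the two in a single score:

    S = Σᵢ rᵢ · exp(−dᵢ / d₀)

where, for each peak cluster *i* on a transcript, `rᵢ` is its intensity
(CLIP read count, or the control-normalized enrichment `rᵢ·log₂(rᵢ/cᵢ)`),
`dᵢ` is the distance in nucleotides along the spliced transcript from the
cluster midpoint to a functional **reference position**, and `d₀` is an
exponential decay constant. Transcripts are ranked by `S`; high-ranking
transcripts are the predicted functional targets.

The package also provides:

* **Reference-site selection.** The reference position can be fixed by
  prior knowledge (TSS, translation start/stop, transcription end site)
  or chosen automatically as the anchor whose metagene profile — average
  peak intensity as a function of anchor distance, pooled over
  transcripts — carries the most signal.
* **Decay-constant estimation.** Inverting the weight formula on the
  metagene profile, `d₀ = −d / ln(p_far / p_max)`, where `p_max` is the
  profile maximum (at distance `d_peak` from the anchor), `p_far` the
  density at a far position, and `d = far − d_peak`.
* **Comparator scores.** An expressRNA-style score (intensity summed
  within ±200 nt of the reference) and PPK (peaks per kilobase of
  spliced transcript), for method comparison.
* **Evaluation.** ROC/AUC against stabilized/degraded labels derived
  from knockout or overexpression log fold changes (LFC), Spearman
  correlation across 19 |LFC|-quantile cutoffs, and a one-sided
  Mann-Whitney test for comparing methods across datasets.
* **A seeded synthetic-data generator** that plants a known reference
  site, decay constant and expression coupling, so the whole pipeline is
  testable without any download.

Audience: computational biologists with CLIP-seq peaks (iCLIP, eCLIP,
PAR-CLIP…) for an RBP, who want a ranked functional-target list and a
way to validate it against perturbation expression data.

## Worked example

Simulate a dataset with peaks planted around the transcription end site
(TES) with decay constant 500 nt, then let the model recover everything:

```python
import pandas as pd
from pras import PRAS, SimConfig, simulate_dataset

cfg = SimConfig(seed=42, n_genes=500)
paths = simulate_dataset(cfg, "demo")

model = PRAS.from_files(paths["annotation"], paths["peaks"], paths["control"])
res = model.fit(ref_site="auto", estimate_decay=True)
print(res.summary(5))
```

```
Protein-RNA Association Strength
================================================
transcripts scored:   496
reference site:       TES
decay constant d0:    424 nt (estimated, w=0.115)
intensity mode:       raw
flank (expressRNA):   ±200 nt
------------------------------------------------
gene_id transcript_id  pras_score  expressrna_score   ppk  n_peaks ref_site  d0
 G00287        T00287        81.8                88 1.298        5      tes 424
 G00151        T00151       73.61                85 2.154        6      tes 424
 G00198        T00198       69.73                15 2.634        7      tes 424
 G00326        T00326       67.26                66  1.29        5      tes 424
 G00405        T00405       64.24                64 1.366        4      tes 424
```

The model picked the planted anchor (TES) automatically and estimated
`d₀ = 424` nt against a planted 500 nt. Evaluating the ranking against
the simulated knockout expression table:

```python
expr = pd.read_csv(paths["expression"], sep="\t")
ev = res.evaluate(expr, design="ko")
```

prints `AUC = 0.825` for separating stabilized from degraded genes and a
Spearman correlation of −0.69 between score and LFC at the laxest |LFC|
cutoff, strengthening to −0.73 at the strictest — strongly bound
transcripts lose the most expression when the protein is removed, and
the association tightens among the most-changed genes.

The same pipeline is available from the shell:

```sh
pras simulate --seed 42 --n-genes 500 --out-dir demo
pras score --gtf demo/annotation.gtf --peaks demo/peaks.bed \
     --ref-site auto --estimate-d0 --out scores.tsv
pras evaluate --scores scores.tsv --expression demo/expression.tsv --design ko
```

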