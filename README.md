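# embryofish

Quantitative analysis of graded morphogen responses from single-molecule
FISH (smFISH) images of early *Drosophila* embryos — spot detection,
transcription-site (TS) quantification, stochastic promoter-activation
modeling, and forward simulation of mRNA accumulation and intron delay.

## The scientific problem

The nuclear gradient of the NFκB-family transcription factor Dorsal is
the only dorsoventral asymmetry cue of the blastoderm embryo. Within the
~20 nuclear columns of the future mesoderm, genes that drive graded
actomyosin constriction (*T48*, *mist*) accumulate mRNA in a ventral-peaked
gradient. This package implements the analysis chain that dissects how
that gradient arises from smFISH snapshots, and the models that explain it:

* **Activation probability.** Each gene locus (allele) switches on
  permanently and stochastically with a per-minute probability
  *p(x) = p₀·D(x)* proportional to the local nuclear Dorsal level *D(x)*
  (midline = 1). After *T* minutes of exposure to the stable gradient the
  activated fraction at column *x* is

      F(x) = 1 − exp(−T·p(x)),

  so an observed fraction inverts to *p̂ = −ln(1−F̂)/T*. A
  Dorsal-proportional *p* makes both *F̂* and *p̂* linear in *D*; a
  switch-like uniform *p* (the *twi* mode) makes them flat.
* **Pol II loading.** A cytoplasmic smFISH spot is one mature transcript,
  so the ratio *R* of the median cumulative TS intensity to the median
  cumulative single-mRNA intensity estimates the number of engaged
  Pol II complexes *N* per active locus; *1000·L/N* is their genomic
  spacing in bp for a gene of length *L* kb.
* **mRNA accumulation.** With stable transcripts and production rate
  *r(x)* per active locus, the expected accumulated mRNA is
  *M(x,t) = r(x)·[t − (1−e^{−p(x)t})/p(x)]* — graded through activation
  timing alone (*r* ≡ 1) and sharper with Dorsal-graded loading
  (*r(x) = D(x)*).
* **Intron delay.** Pol II elongates at ~2 kb/min; the ~25 kb intron of
  the 29 kb *T48* gene delays the first mature mRNA by 12.5 min relative
  to the 4 kb intronless cDNA, timing translation to the end of
  cellularization.

Because no raw image data is distributed, the package ships a synthetic
embryo generator (`embryofish.synthetic`) that renders DAPI + smFISH 3D
stacks with planted, fully known ground truth; every stage of the
pipeline is validated against it.

## Worked example

The numbered scripts in `analysis/` run the full chain on the default
synthetic embryo (seed 7); intermediates land in `scratch/pipeline/`,
tables in `results/`. `python analysis/01_simulate_embryo.py` through
`06_simulate_expression.py` print, in order:

```
rendered 152 nuclei over 19 columns
planted 125 transcription sites and 380 cytoplasmic mRNAs
...
TS/mRNA median intensity ratio R = 69.9 (planted 70) -> ~70 Pol II per active T48 locus
on a 29 kb gene that is one Pol II every 415 bp (~400 bp)
...
model-level (200 nuclei/column, 20 seeds): r(F,D) = 0.987, r(p,D) = 0.992 under p ~ Dorsal
switch-like control (uniform p): r(F,D) = -0.004
...
accumulated-mRNA correlation with Dorsal: constant loading r = 0.981, graded loading r = 0.994
first mature T48 mRNA 14.5 min after activation (cDNA: 2.0 min) -> intron delay 12.5 min
```

Reading: the detection + classification chain recovers the planted
TS-to-mRNA intensity ratio (70) to within a percent, which translates to
one Pol II complex every ~400 bp on *T48*; simulated activated fractions
and inverted probabilities correlate almost perfectly with the Dorsal
profile when — and only when — the activation probability is
Dorsal-proportional; and the intron delay falls in the 10–15 min window.

The same stages are available as a CLI
(`embryofish run-all --seed 7 --out-dir scratch/pipeline`, or stage by
stage: `simulate-embryo`, `detect-spots`, `geometry`, `quantify`,
`fit-activation`, `simulate-expression`, `report`).

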