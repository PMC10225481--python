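# oriseek

Prediction and analysis of bacterial replication origins (*oriC*) in complete
and draft genomes.

Bacterial chromosome replication initiates at *oriC*, a locus that typically
sits in an intergenic region, carries a cluster of DnaA-protein binding sites
(DnaA boxes), an AT-rich DNA unwinding element (DUE), and lies next to the
*dnaA* gene near the minimum of the cumulative GC disparity (the Z-curve
signature of replichore strand bias). `oriseek` turns those signals into a
quantitative prediction: it extracts every intergenic sequence (IGS) of a
genome, scores each one, ranks the candidates, annotates the functional
elements of the winner, predicts the replication terminus, and computes
leading/lagging-strand bias statistics. For whom: microbial genomicists who
need *oriC* and replichore annotation for newly assembled (complete **or**
draft) genomes, and anyone building *oriC* datasets for comparative analysis.

## The scoring model

Each IGS receives three additive components, each in [0, 1]:

* **s_dist** (base composition). With *d* the distance (circular where
  applicable) from the IGS midpoint to the GC-disparity minimum of the
  replicon, `s_dist = max(0, 1 − d/(L/2))`.
* **s_gene** (indicator genes). 1.0 if a principal indicator gene (*dnaA* by
  default; *repA*/*rctB* on secondary replicons) immediately flanks the IGS;
  0.75 for a secondary-indicator flank; 0.5 if any indicator lies within
  5 kb; else 0.
* **s_box** (DnaA boxes). Every box hit with *m* ≤ *k* mismatches from the
  configured motif (E. coli `TTATCCACA` by default, *k* = 1) contributes
  `(k+1−m)/(k+1)` box-equivalents; the component saturates at a cluster of
  three: `s_box = min(Σ/3, 1)`.

`total = s_dist + s_gene + s_box ∈ [0, 3]`. The top-ranked IGS is the
predicted *oriC*; exact ties are screened by DnaA-trio arrays, then GATC
(Dam) site counts, then AT fraction, and all co-ranked winners are reported
(chromosomes can carry multiple origins). Draft genomes are scored per
contig against that contig's own GC-disparity minimum and length, then
pooled. The terminus comes from a user-configured *dif* motif when one
matches, otherwise from the GC-disparity maximum.

Annotated elements: DnaA boxes (plus weakly conserved boxes with ≤ 4
mismatches adjacent to DnaA-trios, labeled for display only), DnaA-trio
tandem repeats (`GAT` units), ATP-DnaA boxes (`AGATCT`), Dam methylation
sites (`GATC`), CtrA motifs (`TTAA-N7-TTAA`), a windowed AT-richness DUE
proxy, and any user-supplied motifs.

## Worked example

```bash
oriseek simulate --length 50000 --seed 5 --out fixtures/
oriseek predict --input fixtures/sim5.gbk --strand-bias --out run/
# predicted oriC: sim5:1..150 (total score 2.997)
```

The simulated chromosome plants an origin IGS at position 1–150 with three
exact DnaA boxes, a DnaA-trio run, an AT island and a *dnaA* flank, plus a
leading-strand GC skew of 0.04 switching sign at the terminus. The printed
line is the rank-1 candidate: it is the planted interval, and its score
decomposes as `s_dist = 0.997` (midpoint 75 bp from the GC-disparity
minimum), `s_gene = 1.0` (*dnaA* flank), `s_box = 1.0` (three exact boxes).
`run/` then contains:

* `result.json` — predictions with 1-based coordinates, component scores,
  element annotations, terminus, strand-bias block, run metadata
  (seed + config hash);
* `candidates.tsv` — every scored IGS, one row each;
* `elements.bed` — BED6 of the predicted *oriC*, its elements and the
  terminus;
* `curves.tsv` — the AT/GC/RY/MK disparity curves for plotting;
* `oric_annotated.txt` / `.html` — the *oriC* sequence with inline element
  labels, e.g. `[DnaA_box|TTATCCACA]`; stripping labels restores the raw
  sequence.

The same pipeline is importable: `oriseek.predict_oric`,
`oriseek.predict_oric_draft`, `oriseek.predict_terminus`,
`oriseek.compute_strand_bias`, `oriseek.simulate_genome`.

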