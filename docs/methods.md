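# Methods

## Problem and model

`oriseek` predicts the chromosomal replication origin (*oriC*) of a
bacterial genome from sequence alone (optionally with annotation). It rests
on three well-established observations: (i) replichore strand asymmetry
places the minimum of the cumulative GC disparity near *oriC* and its
maximum near the terminus; (ii) *oriC* is usually an intergenic locus
adjacent to the *dnaA* gene; and (iii) it carries a cluster of DnaA boxes
together with accessory elements (DnaA-trios, ATP-DnaA boxes, Dam/GATC
sites, regulator motifs, an AT-rich unwinding element). The predictor is a
deterministic scoring pipeline, not a fitted statistical model: no training
data enter it, and every run is reproducible from the inputs and the
configuration.

### Disparity curves

For a sequence of length L the package computes four prefix-cumulative
curves (index n = first n bases): AT (A−T excess), GC (G−C excess),
RY (purine−pyrimidine) and MK (amino−keto). By construction RY = AT + GC
and MK = AT − GC at every prefix; N contributes zero. Extrema of the GC
curve are taken on the given linearization with ties broken by the smallest
index; rotation of a circular replicon is treated purely as a display
transform. No smoothing is applied before extremum-finding (a windowed mean
is available for plotting only): rearranged genomes can fluctuate near the
extrema, and any de-noising rule would be arbitrary — instead the scoring
combines the curve evidence with gene and motif evidence, which is exactly
the situation the three-component score is designed for.

### IGS scoring

Every maximal annotation-free interval (IGS) of at least `min_igs_len` bp
(default 80 — comfortably admitting known origins of a few hundred bp while
suppressing micro-gaps) is scored:

* `s_dist = max(0, 1 − d/(L/2))`, d = (circular) distance from IGS midpoint
  to the GC-disparity minimum. On drafts, d and L are the contig's own.
* `s_gene`: 1.0 primary-indicator flank > 0.75 secondary flank > 0.5 any
  indicator within 5 kb > 0. The 5-kb radius operationalises "adjacent to
  *dnaA*"; flanking always beats proximity. Proximity is measured from the
  gene midpoint to the nearest point of the IGS interval. Indicator matching
  is case-insensitive on the gene name and whole-word on the product string,
  so unannotated gene names still match via products such as "chromosomal
  replication initiator protein DnaA". On `chromosome_type="secondary"` the
  tiers swap (repA/rctB become principal), reflecting DnaA-independent
  initiation of secondary replicons.
* `s_box = min(Σ (k+1−m)/(k+1) / 3, 1)` over box hits with m ≤ k mismatches
  (k = 1 by default). A perfect box counts 1 box-equivalent, a 1-mismatch
  box half. Saturation at three box-equivalents encodes "a DnaA box
  cluster" without rewarding arbitrarily box-rich repeats.
* `total` is the weighted sum (default weights 1,1,1), so total ∈ [0, 3].

The exact constants (0.75/0.5 tiers, 5-kb radius, three-box saturation,
k = 1) are this package's normative definition of the score; they are design
choices where the underlying idea fixes only the ordering of the evidence
classes.

Ranking is by total, with exact ties screened in order: more DnaA-trio
arrays, more GATC sites, higher AT fraction, smaller start coordinate (and
input contig order when pooling drafts). All exactly co-ranked winners are
reported — multiple origins per chromosome are a real phenomenon — and the
reporting margin ε is configurable (default 0, exact ties only). Candidates
with total ≤ 0 are never reported. Adjacent high-scoring IGSs are not
merged; bipartite origins appear as two candidates.

### Motif scanning

Patterns are IUPAC strings; a sequence base matches a pattern symbol when
its possibility set is a subset of the symbol's set. Hence pattern N matches
anything at zero cost while sequence N mismatches every pattern symbol
except N — an unknown base never fabricates motif evidence. Scanning is
vectorised over all windows with 4-bit base masks; minus-strand hits are
found by scanning the reverse-complemented pattern and reported in forward
coordinates. All overlapping hits are kept. CtrA's `TTAA-N7-TTAA` spacer is
all-N, so its mismatch budget (default 1) can only be spent in the half
sites. GATC and AGATCT are palindromic and are deduplicated to one hit per
forward position. DnaA-trios are maximal tandem runs of ≥ 3 exact `GAT`
units (unit, count and the 50-bp box-linkage gap are configurable; the
defaults follow the B. subtilis description of the basal unwinding system);
a weakly conserved box with ≤ 4 mismatches adjacent to a trio run is labeled
in annotation output but never scored. Only three DnaA-box consensi are
shipped (E. coli TTATCCACA, Cyanobacteria TTTTCCACA, T. maritima
AAACCTACCACC); other species-specific boxes, dif motifs, and Fis/IHF sites
are user-suppliable, since no broadly agreed consensus exists to hard-code.

The DUE is located by a sliding-window A+T fraction (window 30 bp, step 1);
the argmax window is annotated as the putative unwinding element. This is a
deliberately simple duplex-stability proxy: it captures AT-rich islands but
not superhelicity-dependent destabilisation.

### Terminus and strand bias

For a complete genome the terminus is the midpoint of the best dif-motif hit
(fewest mismatches, then nearest the GC-disparity maximum) when a dif motif
is configured and matches within 2 mismatches; otherwise the GC-disparity
maximum. Replichore arcs are [oriC, ter) and [ter, oriC) mod L; a gene is
leading when transcribed co-directionally with its fork (forward genes on
arc 1, reverse genes on arc 2), classified by midpoint (boundary-straddling
genes are rare and the midpoint rule is deterministic). Reported "strand
lengths" are the two arc lengths — the note is repeated in the output
because other definitions exist. The leading strand sequence is arc 1
forward plus the reverse complement of arc 2. Only CDS/ORF features are
counted by default.

### Input handling

FASTA and GenBank flat files are read through Biopython. Internal
coordinates are 0-based half-open; all user-facing output is 1-based
inclusive. FASTA topology defaults to linear with a `--circular` override;
the GenBank LOCUS topology wins when present. IUPAC ambiguity codes in input
collapse to N; anything else is an input error naming the character and
line. Wrap-around (`join`) features are split at the coordinate origin;
features exceeding the sequence are dropped with a warning. For unannotated
input a six-frame ORF fallback (ATG/GTG/TTG to in-frame stop, ≥ 300 nt,
longest per stop) delimits the IGSs; it is a crude gene-caller stand-in
whose only job is interval delimitation, and its ORFs never match indicator
names. All annotated gene/CDS features delimit IGSs.

## Synthetic genomes

The simulator generates the study conditions the tests and the acceptance
sweep run under: circular chromosomes of L = 200 kb (default) with the
origin at coordinate 0 and terminus at L/2; per-arc base probabilities
shifted ±skew/2 so the leading strand carries a G−C frequency excess equal
to `gc_skew` (default 0.04) and a T−A excess of `at_skew` (default 0.02);
900-bp placeholder genes (random sequence — the predictor uses only
coordinates) separated by 150-bp gaps; and a planted origin IGS containing
three exact DnaA boxes, a 3-unit GAT trio run and a 30-bp island of AT
fraction 0.9, with a *dnaA*-named flank gene. The defaults are mid-range for
real bacterial chromosomes: GC skews of a few percent, ~1 gene per kb, and
an E. coli-like origin architecture. L = 200 kb rather than a full-size
chromosome keeps a 100-genome sweep fast while leaving the skew signal
overwhelming relative to random-walk noise (the GC-curve extremum
concentrates within ~10^3 bp of the true switch point at this skew). The
planted-IGS filler is redrawn until the interval carries exactly the
intended number of exact boxes, so truth is unambiguous.

What the simulator does **not** emulate: genome rearrangements (which
flatten or multiply disparity extrema), species-specific box variants,
skews near zero (Cyanobacteria-like genomes), RNA genes, overlapping genes,
and annotation errors. Passing the planted-origin sweep therefore shows the
pipeline recovers a canonical origin architecture under realistic noise; it
does not bound accuracy on atypical real genomes.

`split_genome` cuts a simulated chromosome into linear contigs at
intergenic midpoints nearest evenly spaced targets (skipping the planted
interval) for draft-mode consistency checks.

## Numerical and degenerate-input choices

* All extremum and ranking ties break toward the smallest index/start —
  determinism over arbitrariness.
* A featureless record is one whole-length IGS; an all-coding record yields
  an empty prediction with a warning, not an error.
* Score components are exact rational arithmetic in floating point (sums of
  small fractions); the worked examples reproduce to machine precision.
* The flat-curve degenerate case (e.g. poly-A) gives min = max = 0 by the
  tie rule; terminus prediction then coincides with the origin position,
  which the replichore partition rejects explicitly.

## Known limitations

* The score weights (1,1,1) are unvalidated against curated origin
  databases; they encode "all three evidence classes matter equally".
* The ORF fallback over-calls ORFs relative to a real gene finder, which
  shortens IGSs; with annotation available, GenBank input is preferable.
* Terminus prediction without a dif motif inherits the GC-curve's
  sensitivity to rearrangement.
* Draft mode pools per-contig scores but attempts no scaffolding; origins
  split across contig boundaries are missed.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run: 100-genome sweeps at
L = 200 kb (complete + terminus + 3-contig draft per genome), 200 random
motif-scanner oracle cases, 1000 random-sequence disparity-identity checks,
and the three worked scoring examples. The full suite runs in well under a
minute on one CPU.
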