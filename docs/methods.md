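# Methods

## Scope and model

`memevo` analyses the molecular evolution of the residues at the
lipid-water interface (LWI) of a polytopic membrane-protein family, and of
its cholesterol-recognition motif regions.  The pipeline consumes a
pre-built multiple alignment (it never aligns), a species/clade metadata
table, a TM topology on one reference sequence, and optionally an HGVS-p
somatic-mutation catalog.  All coordinates are 1-based inclusive on the
reference; a column map (built from the reference row of the alignment)
projects reference coordinates onto alignment columns.

### LWI regions

The lipid-water interface is operationalized as the `flank_width` residues
(default 5, roughly the 6–10 Å boundary zone of an extended chain)
immediately *outside* each end of each TM helix.  The alternative reading —
the terminal five residues *inside* the helix — is available via
`lwi_inside_tm=True` for sensitivity analysis; the flank-outside convention
is the default because the interface belongs to the boundary layer the
helix ends project into.  Leaflet labels (inner = cytoplasmic, outer =
extracellular) follow deterministically from the membrane side of the N
terminus: the chain flips sides at every TM crossing, so the N flank of TM
*i* lies on the pre-crossing side and its C flank on the post-crossing
side.  Flanks of helices separated by short loops may overlap; they are
reported per region, so a six-TM topology always accounts 12 regions and 60
region-residue *slots*, with unique-residue counts reported separately.

### Motif scanning

CRAC (`[L/V]-X(1-5)-Y-X(1-5)-[R/K]`), CARC (the same pattern read C→N:
`[R/K]-X(1-5)-Y-X(1-5)-[L/V]`) and CCM (`[R/K]-X(2-6)-[I/V/L]-X(3)-[W/Y]`)
are matched by *exhaustive* enumeration of admissible anchor triples, not
by leftmost-greedy regular-expression search: with variable gaps,
occurrences overlap and nest, and published motif tables include
overlapping occurrences.  `collapse="spans"` (the default reporting unit
for motif counting) merges matches sharing a (start, end) span;
`"anchors"`/`"none"` report each triple.  The CARC central anchor is strict
`Y` by default (`carc_central="YF"` enables the widened literature
variant); the CCM `X(3)` is exactly three wildcards.  Per-kind ordinals
(CARC1, CARC2, …) are assigned by start, ties broken by end.  Correctness
is pinned by an O(n³) brute-force oracle and a CARC↔CRAC reversal-duality
property in the test suite.

### Conservation statistics

Divergence of a region is the bootstrap distribution of the mean over all
unordered sequence pairs of the p-distance (mismatch proportion, pairwise
gap deletion) computed on `len(columns)` columns resampled with
replacement; 1000 replicates by default, one seeded NumPy generator, the
seed recorded in every output.  The p-distance (rather than a
Poisson-corrected distance) is used because the statistic feeds a
rank-based region comparison where monotone corrections change nothing.
Per-column information content is log2(20) − Shannon entropy, gaps
excluded, no small-sample correction — the standard logo height.
Two-region comparisons use the Mann-Whitney U test (exact enumeration for
combined n ≤ 12 without ties, otherwise the tie- and continuity-corrected
normal approximation, via SciPy); multi-region comparisons use
Kruskal-Wallis.  A region is called "highly conserved" when its median
bootstrap divergence is below the full-length median — an explicit,
reported criterion of this package.

### Frequency trends

Per-species residue percentages are computed per region class (inner,
outer, total, N-side, C-side LWI; TM; full length), gaps and ambiguity
codes excluded from denominators.  Species-level values are the units for
all between-group tests (pooled-residue percentages are available as an
alternative).  Trends across the clade order amphibian → reptile → bird →
mammal are classified per residue:

* `excluded` — zero in every species;
* `positive_selection` / `negative_selection` — Spearman correlation of
  per-species percentage against clade rank significant at `alpha`
  (default 0.05), signed;
* `conserved` — otherwise, if the coefficient of variation of clade means
  ≤ `cv_max` (default 0.5);
* `variable` — otherwise.

Non-excluded residues are tagged above/below/equal relative to a
background composition (bundled UniProtKB/Swiss-Prot average; replaceable)
with a relative tolerance band of `natural_tol` (default ±20%).  These
thresholds operationalize what frequency plots are usually judged on by
eye; they are deliberate package choices and all sit in the configuration.
Hydropathy classes follow the membrane-frequency-analysis convention
(W,F,Y,L,I,C,M hydrophobic; A,R,N,D,Q,H,P,S,T,K,G,V hydrophilic); Glu is
not in either printed list, so it is kept unassigned by default and
reported separately (`with_glu_hydrophilic()` folds it in).  Charge-class
and hydropathy ratios are reported in both orientations, explicitly named,
because published ratio values are ambiguous about orientation.

### Mutation overlap

HGVS-p strings (`p.R842K`, `p.S902*`, `p.Y905=`; whitespace and
parentheses tolerated) are parsed into records that round-trip through a
canonical formatter; malformed entries are flagged, counted, and never
silently dropped.  The counting unit is the distinct protein-level change;
duplicate raw strings are de-duplicated with a logged count (switchable).
The Venn summary (in motif / in LWI / both / neither, by position
containment) enforces its identity `n_total = neither + motif + lwi −
both` as a class invariant.  Whether published Venn counts de-duplicate
multi-sample entries is generally unstated, so both counting modes exist.

## Synthetic families

The generator emits study-scale families: by default 67 species (8
amphibians, 12 reptiles, 17 birds, 30 mammals), a 1104-residue protein
with six 21-residue TM helices (cytoplasmic N terminus) in its C-terminal
half, and a mammalian reference (`mammal_01`).  TM columns evolve at a 2%
substitution rate over a hydrophobic pool, loop columns at 10% against the
background composition, and LWI columns are drawn i.i.d. per species from
clade-specific target distributions — the mechanism by which exclusion
(Ala/Cys everywhere; His/Met outer; Glu/Gln/Pro/Asn/Ile/Phe inner),
positive selection (Val outer, His inner), negative selection (Ile outer,
Arg inner) and conserved frequencies are planted.  The inner-leaflet
targets carry the positive-charge excess characteristic of cytoplasmic
flanks (positive ≈ 18%, negative ≈ 11%, ratio ≈ 1.6).  Motifs are planted
verbatim in loop territory and held invariant across species; planting one
on an LWI or TM column is rejected as infeasible rather than silently
degraded.

What the generator does *not* emulate: phylogenetic correlation (species
are i.i.d. within clades — no tree), rate heterogeneity, indels (off by
default; an indel mode inserts reference-gap columns solely to exercise
the column map), and *positional* conservation within LWI flanks — LWI
columns are compositionally structured but column-wise random, so their
bootstrap divergence is high by construction.  Passing tests therefore
demonstrate correct recovery of compositional and geometric structure, not
realistic evolutionary dynamics; conservation-ranking behaviour is instead
pinned with the near-invariant control fixture (a synthetic histone-H4-like
alignment, each sequence ≤1 substitution) against its column-shuffled
negative control.

## Numerical choices and degenerate inputs

* Bootstrap replicates with no comparable (gap-free) pair-column yield NaN
  and are excluded from the replicate mean; an all-gap comparison returns
  a NaN p-distance rather than 0.
* Spearman on constant values is defined as ρ = 0, p = 1 (no trend).
* Ratio denominators of zero yield NaN, never infinity.
* `classify_trend` with a missing clade or fewer than two species per
  clade skips the trend test, notes it, and falls back to the
  exclusion/conservation rules.
* All stochastic outputs (bootstrap, generator) take explicit integer
  seeds and are bit-for-bit reproducible; the pipeline manifest records
  every seed, and reruns are byte-identical.

## Problem sizes

The bundled acceptance script (`scripts/acceptance.py`) regenerates the
default 67-species family, scans the full reference, classifies all 60
trend calls, runs 300-replicate bootstraps, and cross-checks the scanner
against the cubic oracle on 120-mers — a few seconds end to end.  The test
suite's oracle equivalence goes up to n = 200 sequences and the
law-of-large-numbers check to 10,000 replicates.

## Known limitations

* Trend classification assumes the four-clade ladder; other orderings
  require passing `clade_order`.
* The Spearman trend test treats species as exchangeable within clades;
  phylogenetic non-independence inflates the effective significance on
  real data (a permutation check of the type-I rate is in the tests, but
  only under the i.i.d. generator).
* TM boundaries are consumed, never predicted; truncated flanks at the
  protein ends must be explicitly allowed.
* The background composition is a database-wide average; membrane proteins
  deviate from it, so above/below-natural tags should be read against a
  user-supplied baseline when one exists.
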