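# Methods

## Per-site quantification

Base counting at catalogued sites follows the standard pileup convention
for editing analysis. A base enters the tally only if its phred quality is
**strictly greater** than `min_phred` (default 25; a phred-25 base fails),
the read is mapped, primary and — unless the unique filter is disabled —
carries `NH:i:1`. Reads with a deletion or reference skip across the site
contribute nothing. Minus-strand sites (plus-strand reference T) are
counted in complemented space, so `n_A`/`n_G` always refer to the annotated
strand. Duplicate catalog rows collapse to one site with a logged warning.

Two denominators coexist deliberately. The per-site editing level is
`n_G / (n_A + n_G)`, the convention of site-level editing tools; the
conserved-editing index divides by **all** filtered bases at the site
(`n_total`, including C/T noise), which is the aggregate-index convention.
They differ only at sites with non-A/G noise, and both are reported.

The coverage rule (`min_coverage` = 15 reads, `min_groups` = 2) mirrors the
purified-cell-type study design: a site must reach coverage in at least two
sample groups, where a group qualifies if any of its samples does; sites
failing the rule are removed from the level matrix entirely, while
per-sample shortfalls are marked missing with a reason code. When fewer
groups exist than `min_groups` (single-sample runs), the rule degrades to
"all available groups". Amplicon (mmPCR-style) input reuses the same
operations with the unique-mapping filter off, and the CEI offers an
equal-weights variant (mean of per-site ratios) beside the default
depth-weighted form, since amplicon panels have no natural coverage
weighting.

The host-gene dominance QC flags a sample when its top gene strictly
exceeds 70 % of summed FPKM over the panel's host genes (the
endothelial/IGFBP7 situation); flagged samples are marked in the pipeline's
CEI table and excluded from summaries.

## Repeat (SINE) editing index

Repeat intervals are read from 6-column BED (0-based half-open, strand in
column 6). Overlapping same-strand intervals merge; intervals overlapping
on opposite strands are dropped with a logged count, because the A-strand
would be ambiguous. Every filtered read base over a repeat position with
reference X increments `denominator(X)`, and `numerator(X→Y)` when the read
base differs; minus-strand repeats are counted in complemented space, so
the A→G entry always measures sense-strand A→G. All 12 ordered mismatch
indices are emitted, as fractions and ×100, with per-sample signal-to-noise
(A→G over the median of the other 11; `inf` sentinel when the noise median
is zero). Rescued hyper-edited alignments may be merged in; they pass the
same filters.

## Hyper-editing rescue

The rescue aligner collapses the A/G distinction: reads and genome are
rewritten A→G (sense) and, in a second index, T→C (antisense editing as it
appears on the plus strand), then matched by exact 16-mer seeds taken at
the read start, middle and end, and extended ungapped. A candidate is kept
at ≤ 2 transformed-space mismatches; multiple equally good loci — including
sense/antisense ties — make the read ambiguous and it is discarded. The
internal aligner exists so the pipeline is self-contained on synthetic
genomes; externally produced transformed-space alignments can be
substituted.

After back-transformation against the untransformed genome, mismatches
with phred ≤ 25 are ignored; the read is accepted when it shows at least 5
A→G edits, at most 1 other mismatch, and an A→G share of at least 60 %.
These thresholds are configurable; an alternative density criterion
(edits per read length) is exposed but off by default. Antisense calls are
reported in sense space (ref A, alt G). Accepted reads are exportable as
ordinary alignments for index merging, and the sample-level statistic is
accepted reads × 10⁶ / mapped reads.

The neighbor signature compares base frequencies at −1/+1 of accepted
edits (5′→3′ in the edited strand's sense) against all genomic adenosines
on both strands; the reported ratios are site frequency over background
frequency, with G depletion expected upstream and G excess downstream.
Edits at contig boundaries are skipped and counted.

## Composition model

Bulk levels follow
`level(s) = Σ_c f_c w_c(g(s)) L_c(s) / Σ_c f_c w_c(g(s))`.
Expression weighting uses transcript abundance (`f_c · w_c`) because bulk
read counts scale with expression; uniform weights are the fallback and
reduce the model to `Σ_c f_c L_c(s)`. The repeat index mixes with uniform
read-output weights. A neuronal-density change scales `f_neuron` by
`(1 + δ)` and redistributes the remaining mass over other types
proportionally to their baseline fractions.

Differential editing uses the two-sided Mann-Whitney test: full
enumeration of all `C(n, n_x)` group assignments (tie-aware, counting
splits at least as extreme on either tail) whenever `min(n_A, n_B) ≤ 8`,
since injury cohorts have 2–8 replicates and the normal approximation is
poor there; the asymptotic form with tie correction is used above that.
Sites with fewer than two replicates in either group are skipped with a
reason; identical constant groups give p = 1 by convention. Multiple
testing uses Benjamini-Hochberg (Bonferroni by flag), and deltas are
reported in percentage points to match recoding-panel conventions.

Editome clustering computes pairwise Pearson correlation on complete-pair
sites (≥ 3 required), distance `1 − r`, average linkage; the two-group cut
is taken at the tallest merge, which reproduces the binary
neuron/non-neuron reading without free parameters. Trees serialize to
Newick.

The inverse estimator rests on the observation that the mixing equation,
multiplied through by its denominator, is linear and homogeneous in `f`:
`Σ_c f_c w_c(s) (L_c(s) − y_s) = 0` per site. With the simplex constraint
this is an equality-constrained least-squares problem solved through its
KKT system; the residual matrix is rank-deficient by one for exact
mixtures (that null direction *is* the solution), so degeneracy is
diagnosed on the KKT matrix, which becomes ill-conditioned exactly when
cell editomes are collinear. Seven brain cell types are nearly so — the
non-neuron profiles are mutually proportional — which is why fraction
recovery is run on the binary basis: the neuron editome plus the pooled
(baseline-fraction-weighted) non-neuron editome, via `pool_non_neuron`.
Under proportional redistribution the pooled profile is invariant, making
the two-component model exact; recovery of a planted 20 % density drop is
then within ±0.015 per run at 10⁴ coverage per site. The full multi-type
fit remains available and raises the ill-conditioned flag when
appropriate.

A note on orientation: with a density *drop*, injured-minus-control deltas
anti-align with neuron-minus-astrocyte deltas (that is the sign law — sites
high in neurons lose editing). Association strength is therefore reported
as R², and positivity checks orient the injury contrast as editing loss
(control minus injured).

## Synthetic cohort generator

The generator emulates a purified-brain-cell-type study: a small genome
(default 2 × 50 kb, GC 0.42) carrying 20 copies per chromosome of three
200 bp repeat-family consensus sequences (mutual identity < 80 %), each
copy independently mutated at the divergence rate (default 0.1) and
planted inverted with probability 0.35; a catalog of 24 conserved recoding
sites outside repeats (the eight signature genes — six neuron-high, plus
COPA/COG3-like astrocyte-high — then generics; ~25 % on the minus strand,
where the sense adenosine is a plus-strand T).

Editome presets: `"paperlike"` draws, per neuron-high site, a neuron level
from U(0.35, 0.8) and an independent shared non-neuron base level from
U(0.01, 0.25), scaled per type (OPCs the runner-up lineage); astrocyte-high
sites invert the pattern with endothelium second. The independence of the
neuron and non-neuron profiles is what makes non-neuron types mutually
correlated but near-uncorrelated with neurons, the structure that drives
the binary clustering. `"table2"` / `"table2-control"` carry the measured
neuron/astrocyte culture rates of the six-site in-vitro injury panel.
Default repeat-editing rates per cell type span 0.004 (microglia) to 0.02
(neurons). Expression weights default to uniform.

Read simulation draws, per catalog site, Poisson(depth) single-end 100 bp
reads; each read takes a cell type with probability ∝ fraction ×
expression weight, carries the site edit with that type's level (G on plus,
C on minus), then — after all reads exist — repeat edits are planted on
**every** read wherever it overlaps a repeat interval (so the repeat index
is calibrated regardless of why a read was sequenced), sequencing errors
are applied uniformly (each base flipped to a uniform other base with the
error rate), and phred values assigned (constant 35, with an optional
fraction of phred-20 bases to exercise the quality filter). Reads are
emitted as coordinate-sorted SAM with known true positions, because
alignment is out of scope and exact ground truth is the point.
Hyper-edited fragments (6–10 planted A→G edits, enough to defeat a
standard aligner's mismatch budget) go only to FASTQ, with minus-sense
fragments emitted in plus orientation as T→C (orientation is arbitrary in
an unstranded library); an optional neighbor bias plants edits
preferentially after non-G and before G for signature tests, and optional
non-hyper decoy reads (noisy genome fragments and random sequence) test
rescue specificity. The truth table records realized per-site and repeat
edit counts and every hyper read's origin and edit positions. Fixed seeds
give byte-identical outputs. The generator omits splicing, indels, PCR
duplicates and paired ends; none affect the indices under test.

Not emulated from real data: polymorphism (no SNP filtering is needed or
implemented), expression heterogeneity between genes (uniform FPKM unless
specified), mapping ambiguity (all emitted alignments are unique), and
fragment-length effects. Passing tests therefore validate the estimators
and the composition logic, not robustness to alignment artefacts or SNP
contamination.

## Problem sizes and numerical choices

Test and acceptance runs use: toy oracle samples ≤ 50 reads; index
calibration at ~10⁶ repeat adenosine position-bases (error 10⁻³, repeat
editing 0.02, bounds at 3 binomial SD); hyper recovery on ~200 planted
reads plus 2 000 decoys; composition batteries of 20 seeds at 10⁴ coverage
per site, drawn as the binomial sufficient statistic of read simulation
(identical in distribution at zero error, and far cheaper than emitting
~10⁷ SAM records); one full read-level end-to-end run at moderate depth
covers the integration path. The bundled demonstration (4 + 4 samples,
depth 300–400 per site) completes in seconds on one CPU.

Other conventions: all intervals are 0-based half-open internally, 1-based
only in TSV; mixtures must sum to 1 within 10⁻⁹; the Mann-Whitney exact
tail comparison uses a 10⁻⁹ slack to absorb float ties; BH q-values come
from statsmodels; Pearson correlation is undefined (explicit error) under
zero variance; the KKT ill-conditioning threshold is 10¹⁰.
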