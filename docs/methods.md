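# Methods

This note documents the models behind each stage, the defaults and why they
hold, what the simulator does and does not emulate, and the numerical
choices that matter for reproducibility.

## Substitution model and the synthetic genomes

Sequences evolve under a two-rate site model: every site substitutes with
probability `1 − exp(−r·t)` over an interval of `t` My, with
`r = 0.0104`/site/My when the site lies in a CG dinucleotide of the
sequence at the start of the interval and `r = 0.0013` otherwise; the
replacement base is uniform over the three alternatives. These are the two
rates in use for caniform genomes (CpG hypermutability from spontaneous
deamination of methylated cytosine). There are no background indels: the
only structural events are SINE insertions, so orthologous coordinates
drift only through insertions and the flank-mapping stage is tested against
exactly the class of structural difference it must tolerate.

The species tree is the accepted caniform topology
`(((panda, polar_bear), ferret), dog)` with node ages 15.5 My
(panda–polar bear, the usual calibration), 38 My (musteloid split) and
46 My (canid split); the simulated ancestor starts at 60 My so that truly
ancient, universally shared insertions exist. Each subfamily has a source
sequence, an activity window in Mya, an optional lineage restriction, and
an insertion rate per My per active branch. Insertions are a Poisson
process; each copy is the source, 5′-truncated with probability ~0.05–0.1
by a uniform 0–50% of its length (SINE truncation is predominantly 5′; the
severity distribution is our choice), extended by a per-copy (CT)n run and
poly-A tail, reverse-complemented on a random strand, and planted with an
8–15 bp target site duplication copied from the bases immediately 5′ of the
site. Insertions may nest inside earlier elements (splitting the host into
annotation fragments) but never interrupt a previous TSD copy — the site is
resampled — so planted TSDs stay recoverable. The emitted per-species
annotations are truth-derived and RepeatMasker-`.out`-compatible, with the
divergence column holding the true element-vs-copy mismatch percentage so
that the simulator never depends on the divergence estimator it is used to
test.

Two background-composition choices matter. The ancestral genome is
CpG-depleted (80% of CG dinucleotides rewritten to TG/CA), matching the
~0.2 observed/expected CpG ratio of mammalian genomes; with a uniform
background the CpG site fraction triples and cross-species flank identity
at the dog distance (2 × 46 My) falls below the 80% orthology threshold,
which is a composition artifact real genomes do not show. Source sequences
are *not* depleted: young SINEs are CpG-rich, which is precisely what makes
CpG-stratified dating informative. Default insertion rates give roughly
250 panda-branch insertions of the focal family per 2 Mb genome —
statistical power, not an abundance estimate — and scale linearly with
genome length so that smaller simulations keep the same repeat density.

What the simulator does not emulate: assembly gaps and errors, segmental
duplications, deletions and other background indels, recombination,
selection, polymorphism within species, and realistic chromosome counts.
Passing tests therefore demonstrate correctness of the inference machinery
under the stated generative model, not robustness to assembly artifacts or
population-level variation.

## Divergence and element selection

Element-to-consensus alignment is global with affine gaps (+1 match, −1
mismatch, −4 open, −1 extend), ties broken by the aligner's canonical first
traceback. Divergence is the mismatch proportion over substitution columns
only — gap columns excluded — which tracks RepeatMasker's mismatch-based
divergence; a Kimura two-parameter mode is available. A column is CpG when
its consensus base is part of a CG dinucleotide of the ungapped consensus:
hypermutability is a property of the (approximately ancestral) consensus
state, and classifying by the consensus keeps the flag independent of the
element. Per-element divergence is raw (not CpG-adjusted) by default. The
young-element filter keeps a family's elements with total fragment length
and divergence at or inside their thresholds (≥150 bp and ≤10% for the
focal family), boundaries inclusive.

## The lineage-specific screen

Each candidate's 500 bp flanks are located in every target genome by exact
13-mer seeding over a sorted k-mer index, diagonal clustering (clusters up
to 800 bp apart on the diagonal merge, so one structural indel cannot split
a locus), and gapped alignment of the top seeded windows. Identity ≥ 0.80
and flank coverage ≥ 0.90 are required, coverage applied per flank: a query
containing the element itself could never reach 90% coverage at a true
empty site, so flank-wise application is the only self-consistent reading;
presence is decided separately from target annotations.

Four numerical choices make the screen robust at realistic repeat density:

1. **Repeat masking.** Flank positions covered by other annotated repeats
   are hard-masked. Masked bases neither seed nor count toward identity or
   coverage; orthology is judged on unique sequence. Without this, a SINE
   embedded in a flank aligns paralogously to any of its thousands of
   copies — including, worst of all, the target-genome copy of the very
   element under test.
2. **Structural-indel discounting.** Contiguous alignment gap runs of
   ≥ 40 bp are structural (an element present on one side only) and are
   discounted from the identity and coverage denominators. The aligner used
   for any window that could contain such a run scores gaps affinely with
   very cheap extension (−6 open, −0.05 extend, mismatch −2), so a 250 bp
   absent element becomes one long gap rather than a smear of mismatches; a
   unit-cost (edlib) fast path handles the clean cases. Each resulting
   syntenic segment must itself pass the identity threshold, and terminal
   segments must carry ≥ 25 aligned bp — this stops spurious extension
   across an empty site from corrupting the inner coordinates.
3. **Paralogy guard.** A locus is unresolved when a non-overlapping
   alternative hit of comparable aligned mass (≥ 85% of the best hit's
   matched bases) comes within 0.02 identity of the best — the two-copy
   situation where a confident absent call would be unsafe.
4. **Explained gaps.** A locus is absent when both flanks map collinearly
   and the inter-flank gap, minus any bp covered by annotated repeats of
   *other* families, is ≤ 30 bp (inner ends may overlap by up to 50 bp:
   empty sites retain one TSD copy that both flanks can claim). It is
   present when annotations of the same family cover ≥ 50% of the
   inter-flank span. Everything else is unresolved with a reason code.

An element is lineage-specific when its locus is absent in **all** other
genomes; loci unresolved anywhere are excluded and reported separately.
At the default study scale (2 Mb, ~250 planted focal insertions) the screen
recovers ≥ 94% of planted lineage-specific insertions with no false
specifics across seeds; sensitivity degrades gracefully as repeat density
rises, because loci whose flanks are mostly repeat are honestly
unresolvable.

## Target site duplications

The scan compares suffix windows of the left 30 bp flank with prefix
windows of the right, lengths 15 down to 6, offsets up to 5 bp on each side
(annotated boundaries are imprecise), accepting at most one mismatch.
Preference at equal length: exact over one-mismatch, then smaller combined
offset, then smaller left offset. A winning match extends outward while
both copies agree, so lengths beyond the 15 bp search band are reported at
true extent and flagged. The right flank is taken after skipping a terminal
poly-A run of the element (≥ 5 A allowing one other base; poly-T at the
genomic start for minus-strand elements), because Can-SINE tails sit
between the element body and the right TSD copy — and both the trimmed and
untrimmed extractions are scanned with the better call kept, since trimming
can itself consume a TSD that genuinely begins with an A run. Both copies
must lie wholly within the 30 bp windows.

## Subfamily discovery

Elements are globally aligned to a template consensus and projected onto
template columns (insertions dropped, deletions as `-`); elements covering
under half the template are excluded as truncated. Candidate diagnostic
assertions are (column, non-consensus substitution state) pairs carried by
at least `min_size` members — deletions are not diagnostic by default, and
CpG columns are skipped when excluded, since hypermutable sites co-occur by
chance. The most significant co-occurring assertion pair (two-sided Fisher
exact on the 2×2 carrier table, Bonferroni over all tested pairs, α = 10⁻³)
seeds a child subfamily; both consensuses are rebuilt by majority rule
(ties A<C<G<T<−) and every element is reassigned to the nearer consensus
(Hamming; ties to the larger side, then to the lexicographically smaller
consensus), iterated to a fixed point; recursion continues on both sides
until no significant pair remains. A split whose reassigned sides fall
below `min_size` is rejected. All tie-breaks are order-free, so output is
invariant under row permutation. COSEG's triple-cosegregation mode is not
implemented; pairs suffice for the splits exercised here.

A subfamily's reported diagnostics are the columns where its consensus
differs from its parent's. When two subfamilies are compared (as in the
planted-truth checks), the distinguishing columns are where their two
consensuses disagree — at balanced mixtures the pre-split consensus can
side with either source at any one column, so per-subfamily diagnostic
lists split across the two sides while the pairwise difference recovers
the full planted set.

## Median-joining network

Aligned consensuses are compared over complete columns (every sequence
A/C/G/T), optionally excluding CpG columns; duplicates merge into one node
with a multiplicity. Median (Steiner) candidates are quasi-medians of node
triplets — per-column majority, branching over all three states at fully
heterozygous columns — added greedily by the largest reduction in
minimum-spanning weight with lexicographic tie-breaks; medians that stop
reducing the total weight are pruned; the final network is the ε-relaxed
union of all minimum spanning trees (ε = 0 by default, i.e. exactly the
union of all MSTs). This is a deterministic variant of median joining
(classical MJ restricts candidate triplets to connectable nodes); the
variant was chosen because its contract is exactly checkable against an
independent brute-force implementation, which the test suite does on every
small input.

## Ages and activity chronology

Subfamily age uses the class-stratified divergences pooled over members
(counts summed, so short elements do not dominate):
`age_class = −ln(1 − d_class)/r_class`, averaged over the two classes.
The logarithmic form matters for CpG divergences near 0.1 and above, where
the linear `d/r` materially underestimates; both agree for small `d`.

Nested insertions are counted from fragment structure: consecutive
fragments of one element sandwiching complete annotations of another, with
both adjacent fragments ≥ 4 bp (the minimum-repeat-extension rule, read as
a per-fragment bound) and collinear consensus coordinates. Only the
immediate container is credited in a nested chain. The activity model puts
each family's insertion times on a relative timescale, T_f ~ N(μ_f, σ_f²),
with expected nest counts `E[N_fg] = k·a_f·a_g·P(T_g > T_f)` (a = family
abundance); {μ, σ, k} maximize the Poisson likelihood of the observed
matrix by multi-start L-BFGS-B with seeded starts, the gauge fixed to
mean-0, variance-1 μ. Reported intervals are the central 75% and 99% of
each fitted Gaussian, larger μ meaning more recently active. The scale is
relative only: no absolute calibration is attempted (the 15.5 My
panda–polar bear split is carried as config metadata only).

## Pipeline

All stage parameters live in one config with the standard operating
defaults (flank 500 bp, identity 0.80, coverage 0.90, empty-gap 30 bp, TSD
band 6–15 with one mismatch, subfamily minimum 10, rates 0.0013/0.0104,
TinT extension 4). A run writes per-stage TSVs plus a manifest with the
seed, a parameter hash and a SHA-256 per output file; identical config and
seed reproduce byte-identical outputs. Degenerate situations fold to
explicit states rather than errors: an all-zero nesting matrix skips the
activity fit with a message, an alignment with no substitution columns
yields an undefined (flagged) divergence, an empty flank is unresolved with
a reason.

## Problem sizes

The full-scale checks use four 2 Mb genomes (~900 planted insertions,
~250 on the focal branch), 200-element subfamily cohorts, 400 TSD loci,
500-element age cohorts, 100 TinT replicates and networks of up to 6
haplotypes × 8 columns — sizes at which every stage's statistical target is
comfortably identifiable while a complete run stays in the minutes range on
one CPU.
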