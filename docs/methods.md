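# Methods

## The problem

De novo transcriptome projects in non-model organisms (here: the
deep-sea hydrothermal vent mussel *Bathymodiolus azoricus*, gill tissue,
454 pyrosequencing) produce tens of thousands of assembled contigs with
no reference genome. Before any biology can be read off them they must
be triaged: cleaned of library adapters and poly-A tails, assigned a
reading frame, conceptually translated, binned into functional
categories, and screened for sequences of microbial (endosymbiont)
origin. `ventannot` implements that triage as a tested, reusable
pipeline, exercised end to end on synthetic data with planted ground
truth.

## Preprocessing

Adapter removal is Hamming-tolerant terminal matching: an adapter
occurrence at either end, with at most `max_mismatch` substitutions
(default 1), is removed; removal repeats until no terminal occurrence
remains, which makes the pass idempotent. Indels inside adapters are not
modelled — in 454 data substitution-style errors dominate inside the
short synthetic adapter, and an exact-match mode is available by setting
`max_mismatch=0`. Internal occurrences are reported (possible chimeric
junctions) but never cut, since cutting would require a split policy the
downstream accounting does not need.

Poly-A masking lowercases terminal A-runs (3') and T-runs (5', the
reverse-complemented tail) of at least `min_run` bases (default 10,
minimum 5). Masked bases stay in place so coordinates are stable, but
they are excluded from the effective length and read as `N` by the
coding scanner: a masked tail carries no coding signal.

The length gate keeps contigs with at least 40 effective (unmasked)
bases. "Shorter than 40 bp" is read as strictly less-than: a 40-base
contig is kept, matching the assembler's minimum-consensus-length
semantics. Every input contig lands in exactly one of kept /
discarded_short / discarded_empty.

## The frame-assignment cascade

Three tiers, each contig assigned by exactly one or left unassigned:

1. **strict** — a ranked protein-homology hit table (BLASTx tabular
   dialect + frame + subject-taxid columns) is screened at
   E ≤ 10⁻⁶; the frame of the best qualifying hit is adopted.
2. **relaxed** — the remainder re-screened at E ≤ 10⁻².
3. **scan** — the rest handed to a codon-usage coding scanner trained on
   the tiers-1/2 calls.

Ties among qualifying hits are broken by lower E-value, then higher bit
score, then lower rank; frame conflicts are resolved by the single best
hit rather than a majority vote, mirroring a best-hits assessment order.
E-values within a query must be non-decreasing with rank (violations are
input errors naming the query).

### The codon model

An order-0 codon model: log-odds
`ln(p_coding(codon) / p_bg(codon))`, where coding frequencies are
pseudocount-smoothed counts (default pseudocount 1) from the training
set and the background is a mononucleotide model (estimated from the
training contigs unless supplied), whose codon probability is the
product of base frequencies. Training reads each tier-1/2 contig in its
called frame and counts the longest stop-free codon stretch; codons
containing `N` or masked bases are skipped. This is a deliberate
simplification of an HMM-based coding-region finder (ESTScan-style):
the cascade uses the scanner only as a frame detector, and the codon
log-odds core is the part that does that work. A hexamer extension would
slot into the same interface but is not implemented.

Two structural consequences worth knowing:

- Stop codons never appear in stop-free training material, so with
  uniform training codons and uniform background the sense-codon
  log-odds sit at the constant ln(64/61) ≈ 0.048, not exactly 0; the
  tests check flatness against that offset.
- The longest stop-free stretch leaks 5'-UTR codons upstream of the
  true start (the planted stop caps only the 3' side). At the default
  simulation settings this contaminates roughly 10% of training codons
  and moves the estimated joint codon table ~0.07 L1 away from the
  planted one; on clean coding sequences (no UTRs) the same estimator
  recovers the table to ~0.03 L1 at 50k+ codons. Both numbers are
  computed and reported by `scripts/acceptance.py`, not assumed.

### Scanning and null calibration

Each of the six frames is split at stop codons; the best-scoring
stop-free window of at least `min_peptide` codons (default 30 — shorter
windows are never candidates) competes across frames. The winner is
called iff its summed log-odds reaches `score_threshold`. The default
threshold is the 99th percentile (computed as an attained order
statistic, `numpy` method `higher`) of window scores on sequences
simulated from the background model, with lengths drawn from the input
pool (default 1,000 simulations, seed-controlled). By construction the
false-call rate on background sequences then sits at ~1%; a finite
evaluation sample fluctuates around that boundary, so the acceptance
test bounds the measured rate by 1% plus three binomial standard
errors rather than by the boundary itself. Contigs shorter than
3·`min_peptide` bases are unassigned without error.

## GO propagation counting

The ontology is an is_a DAG with exactly one root per namespace
(biological process, molecular function, cellular component); `part_of`
and other relations are ignored. Counting follows the true-path rule
with once-per-product deduplication: for each product the union of
ancestor closures of its terms is intersected with the reporting
categories, and the product contributes at most 1 per category. The
reporting level defaults to depth 1 (direct children of each root),
which is the granularity of typical broad-category pie charts; it is a
parameter because nothing pins the level. Per-namespace percentages use
the sum of category counts as denominator — a product in k categories
contributes k — so percentages per namespace sum to 100 even though a
product-based denominator would not. Products reaching only a root are
reported separately ("root-only"); assignments to unknown terms are
skipped, warned about, and tallied.

## Bacterial fingerprint

A hit is bacterial when the parent chain of its subject taxid (from the
`staxid` column; live identifier-to-taxon services are out of scope)
reaches a rank=superkingdom node named Bacteria. The fingerprint is the
cumulative curve f(r) = number of queries whose best (lowest-rank)
bacterial hit has rank ≤ r, over ranks 1..20. "Best hit position" is
read cumulatively because only a cumulative curve makes a "convergent
number" of bacterial contigs well-defined. The plateau detector reports
the earliest rank r where the next `window−1` increments (default
window 5) are all ≤ `tol` (default 0), plus f(20) as the plateau value
and a non-converged flag when no such rank exists; since no published
convergence criterion exists, both the increments and the flag are
always emitted. Unresolvable taxids skip the hit and are counted.

## Cross-database comparison

One-directional by default (query set A against subject set B): an A
protein is matched iff both sides carry a domain annotation and some hit
passes E ≤ 10⁻⁵ and bit ≥ threshold (defaults 90/120/200; boundaries
inclusive on both gates — the convention is a choice, stated in the
contract and tested at the boundary). Shared-GO percentages are
100·shared/total per category, computed in exact decimal arithmetic and
rounded half-up to one decimal; total 0 reports not-applicable rather
than 0.

## ddCt expression

Classic comparative-CT with amplification efficiency fixed at 2 (an
efficiency-corrected base is an option): ΔCt = mean Ct(gene) − mean
Ct(reference, default role 28S rRNA); ΔΔCt against a calibrator gene;
fold = 2^(−ΔΔCt). SD(ΔCt) combines the two replicate SDs in quadrature;
the calibrator ΔCt is treated as the fixed baseline, and the reported
fold interval is 2^(−(ΔΔCt ± SD)). Folds are invariant to adding a
constant to every Ct, and a gene against itself is exactly 1. Any
replicate count ≥ 1 is accepted and recorded.

## The synthetic generator

The generator is the study-conditions definition, not a tuning knob.
Defaults: 1,000 contigs, coding fraction 0.5 (roughly half the real
contig set was translated); per-contig tier mix strict/relaxed/no-hits =
0.47/0.09/0.44 (the published tier proportions); ≤ 25 ranked hits per
query; hit-frame noise 5%; bacterial source fraction 0.16 (≈ the
published bacterial-contig share of protein-matched contigs); UTRs
20–120 bp; ORFs 80–200 codons; poly-A tails on 35% of contigs; the
canonical SMART IIA oligo as the default adapter on each end with
probability 0.3; ambiguity characters at 0.1%; uniform mononucleotide
background. The default codon-usage table gives synonymous codons
geometrically decaying weights (2^0, 2^-1, ... within each family,
normalized), a skew strong enough that coding and background sequence
are statistically distinct, as in real transcriptomes.

Coding contigs are built as 5'UTR + ATG·(usage-sampled codons)·stop +
3'UTR with a uniform amino-acid marginal over the 20 sense families,
placed on either strand; frames use the BLASTx convention (±1..±3),
intervals are 0-based half-open. E-values grow with rank by
exponential increments (rate `evalue_decay`), the only property the
downstream stages use from them. Bacterial-source contigs place their
best bacterial hit at a geometric low rank (≤ 12), so the rank curve
plateaus inside the 20-rank window.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: read-level error profiles and
assembly artifacts (chimeras, collapsed paralogs), realistic protein
subjects or alignment geometry, correlated E-value/bit-score structure,
biased amino-acid composition, organism-specific GC content, and any
real GO or NCBI taxonomy topology (both are small random stand-ins).

## Problem sizes

Defaults were chosen so a full synthetic run (1,000 contigs, 1,000 null
calibrations) completes in a few seconds and the whole test suite in
well under a minute; recovery checks use 400–1,000 contigs and 50k+
training codons, the sizes at which the stated tolerances are
statistically meaningful.

## Known limitations

- One frame call per contig; multiple peptides per contig (which real
  annotation sometimes emits) are out of scope, and the pipeline's
  transcript total is defined as the sum of the three tier counts.
- The scanner has no indel states; frameshifted ORFs are found only as
  truncated windows.
- The published dataset-scale figures (contig totals, database match
  counts, category percentages) depend on the original reads and
  2010-era databases; this package reproduces their arithmetic and the
  method's behaviour under planted truth, not those absolute numbers.
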