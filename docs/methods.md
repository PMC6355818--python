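# Methods

`dupmode` reconstructs how a gene family expanded: it harvests the family
from an annotated genome with a query protein, builds a distance tree, and
assigns every member a duplication mode — tandem, segmental, retro, or
unclassified — from three independent evidence channels. A forward
simulator with known event truth provides the benchmarks. This note
records the models, the defaults and why they were chosen, and what the
benchmarks do and do not show.

## Family harvesting and distances

Candidate proteins are compared to the query with affine-gap alignment
(`Bio.Align.PairwiseAligner`). Protein scoring defaults to BLOSUM62 with
gap open −11 / extend −1 (BLAST convention; a gap of length L costs
`gap_open + L·gap_extend`); DNA scoring defaults to +1/−2 with gaps
−5/−2. Significance uses the ungapped Karlin–Altschul expectation
E = K·m·n·e^(−λS) with fixed published constants (BLOSUM62: λ = 0.3176,
K = 0.134; DNA +1/−2: λ = 1.33, K = 0.621). This is an explicit
approximation of gapped BLAST statistics — E-values are used only as a
cutoff (default ≤ 1e−10), never interpreted quantitatively. Percent
identity counts gap columns in the denominator (BLAST's
"identities / alignment length"); it can be switched to ungapped columns.

Evolutionary distances are Poisson-corrected protein p-distances,
d = −ln(1 − p), with p computed over ungapped columns of a pairwise global
alignment (pairwise, not complete, deletion: no multiple alignment is
built). d is undefined at p ≥ 1 and the code raises there; in practice
family members harvested at E ≤ 1e−10 never saturate.

## Tree building

Neighbor joining follows Saitou–Nei exactly: join the pair minimising
Q(i,j) = (n−2)d(i,j) − R_i − R_j, branch lengths by the two-point
formulas, reduction by the standard average. Ties in Q are broken
lexicographically by the smallest leaf label in each cluster, so output is
deterministic; Q is explicitly symmetrised to remove floating-point
asymmetry from summation order. Negative branch lengths are clamped to
zero (raw value logged). The unrooted result is stored with a trifurcating
root; analyses that need direction (clade extraction, Dollo) use a
midpoint-rooted copy, chosen because no outgroup is assumed. On additive
inputs NJ provably recovers the generating topology; the test suite checks
this against random trees and, for n ≤ 6, against exhaustive least-squares
topology search.

## Duplication-mode classification

Three evidence channels are computed independently, then combined.

**Tandem arrays.** Family genes on one chromosome are chained while
consecutive members are within `max_gap_bp` (default 250 kb) *and*
separated by at most `max_intervening_genes` (default 5) non-family genes.
Chains of ≥ 2 are clusters. Chaining and calling deliberately use two
physical scales: the chain limits are loose so that decayed or interleaved
arrays stay together, but a per-gene *tandem call* additionally requires
the gene to lie within `tandem_call_max_gap_bp` (default 25 kb) of another
member, because unequal crossing-over creates immediately adjacent copies
while an unrelated family gene that merely inserted inside the chaining
window typically sits tens of kilobases away. Each cluster's most-upstream
member is treated as the array founder and keeps whatever mode its own
origin evidence supports (copies insert downstream of their donor under
the unequal-crossing-over convention). Per-cluster leaf sisterhood (the
fraction of members whose tree sibling subtree contains another member) is
reported as a diagnostic, but does not gate calls: a member's leaf sister
stops being its array neighbour as soon as either of them donates a later
copy elsewhere, so sisterhood systematically under-calls old arrays.

**Segmental pairs.** All-vs-all local DNA alignment of the CDSs; a pair is
kept when identity > 80% (strict) and E < 1e−10, both configurable, and
the two genes are not in one tandem cluster. A reciprocal-best flag marks
pairs where each gene is the other's highest-identity partner.

**Retro signatures.** Intron presence is collapsed to a binary character
(≥ 1 intron) and reconstructed on the rooted tree under Dollo parsimony:
introns were gained once ancestrally and can only be lost. The minimum
assignment is the leaf-OR of each subtree; loss edges (parent 1 → child 0)
mark candidate retroduplications. The root state is forced to 1 by default
(the family ancestor carried introns); with every leaf intronless the
single loss is placed on a phantom stem above the root. A free-root option
drops the forcing. Flank scans supply physical evidence: the earliest
A-rich window (15 bp, ≥ 80% A) or A-run (≥ 8) within 300 bp of the 3'
flank, and maximal direct repeats (≥ 8 bp, ≤ 1 mismatch) between the
terminal 100 bp of the 5' flank and the initial 100 bp of the 3' flank.
Because an 8-mer with one mismatch arises by chance in most random
100 bp × 100 bp window pairs, a direct-repeat hit alone is weak; the
pipeline therefore calls a gene's flank evidence positive only when it is
intronless, its poly(A) hit starts within 50 bp of the gene end (a tail
abuts the cleavage site), and a direct repeat exists. Within each Dollo
loss clade, evidenced members take the retro call; a clade with no
surviving evidence keeps the flag on all members (intronlessness alone
then carries it). Evidenced intronless genes outside any loss clade are
also called retro — a retrocopy of an already-intronless gene leaves no
intron-loss footprint for Dollo to see.

**Precedence.** retro > tandem > segmental > unclassified. Per-gene calls
therefore read: pinpointed retro first; then tandem for adjacent non-founder
array members; then any gene with a segmental partner; else unclassified.

## Promoter element scanning

A fixed dictionary of 22 light/temperature-responsive elements (G-box,
LTR, HSE, Sp1, TCT-motif, ...) ships with the package; `(G/A)`-style
alternatives and IUPAC codes expand to literal patterns. Scanning is exact
string matching on both strands by default (element reports are
strand-agnostic), overlaps allowed, palindromes deduplicated by
(element, position). Promoters default to 2 kb upstream, configurable; the
published per-promoter counts of the source survey are not reproducible
because the underlying promoter sequences and extraction window are not
public, so the scanner is validated against a brute-force matcher on
synthetic promoters instead.

## The simulator

`synth_evolve` emulates the inferred history class directly: one ancestor
gene (3 exons of 300/150/300 bp, two 200 bp introns, a clean binary intron
signal) on an 8-chromosome random genome (1 Mb per chromosome), plus decoy
genes every ~20 kb to give family harvesting real negatives and the
intervening-gene rule something to count. Each of `n_events` steps applies
one event — tandem (genomic copy 1.5–8 kb downstream of the donor),
segmental (genomic copy at a uniform random locus on another chromosome),
or retro (spliced CDS + 15 bp poly(A), inserted with a 10 bp target-site
duplication at a uniform random locus) — then evolves every family gene at
`subs_rate_per_site_per_step` (default 0.01, uniform substitutions). The
default scenario runs 12 events, 4 per mechanism, in a seed-shuffled
order. Duplications copy the gene span only: promoters, poly(A) tracts and
TSDs of the donor are not propagated, which is what lets flank evidence
pinpoint true retrocopies among their intronless descendants. Random
insertion sites are drawn by rejection sampling (a 1.1 kb exclusion margin
around family genes protects the 1 kb flanks the scanners read); an
earlier forward-scanning placement was replaced because it parked inserts
preferentially just outside that margin. Optional stressors: one-shot
flank erosion (substitutions in the 1 kb flanks at finalisation) and
independent intron loss (per gene per step, splicing a non-retro gene down
to its CDS — homoplasy for Dollo). Promoter elements from the dictionary
are planted verbatim 200–1000 bp upstream of each family gene at
finalisation. Everything derives from one seeded NumPy generator; reruns
are byte-identical.

What the simulator does **not** model: indels and frameshifts, transposon
capture, partial duplications, alternative splicing, rate variation across
sites or lineages, GC bias, and real intergenic sequence composition.
Passing benchmarks therefore show the inference machinery is correct under
the stated event model, not that real genomes are this clean.

## Benchmarks and their limits

The acceptance checks (and `scripts/acceptance.py`) measure: exact score
agreement with a brute-force alignment enumerator (200 short pairs);
Poisson closed forms; NJ topology/path recovery on 50 additive matrices
plus least-squares-search agreement at n ≤ 6; Dollo agreement with
exhaustive enumeration on 100 trees; per-mode precision/recall of the full
pipeline on the default scenario (exact at the benchmark seed; pooled over
a 20-replicate sweep, where both stay ≥ 0.9 per mode); poly(A)/TSD recall
over 200 planted retrocopies (1.0 with pristine flanks; poly(A) recall
~0.95 at 0.1 subs/site erosion); promoter-scanner equality with a naive
matcher on 1,000 promoters; the 480-column/24-mismatch = 95.0% identity
worked example; and byte-identical reports across reruns.

Two failure modes are irreducible from tree + locus evidence and are
accepted: a segmental or retro copy that lands within the tandem-call
distance of an array (or of its own donor) is indistinguishable from a
tandem copy; and at divergences where E-value harvesting saturates
(≳ 1 substitution/site) the family itself is no longer recoverable. The
pooled sweep quantifies the first (~1% of events at default conditions);
the second bounds the divergence regime the pipeline addresses.

## Numerical and formatting choices

GFF3 1-based inclusive coordinates everywhere; BED export converts to
0-based half-open. FASTA written at 60 columns, LF endings. Codons with N
translate to X rather than erroring (draft-assembly tolerance); internal
stops are kept as `*` and flagged. Reports embed a config hash and seed,
never timestamps, so identical runs produce identical bytes. Metrics
conventions: precision (recall) of a mode with no predictions (no true
events) is 1.0; only the *new* gene of each simulated event is scored —
the donor's label belongs to the event that created the donor.
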