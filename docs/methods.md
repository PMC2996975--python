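# Methods

## Data model and coordinate conventions

Genomes are circular, annotated records with 1-based inclusive coordinates.
A feature wrapping the coordinate origin is stored as two intervals
`(a, L), (1, b)`, never as `start > end`. Strand `H` is the strand read in
increasing coordinates (the strand carrying tRNA-Phe next to the control
region in the typical arrangement), `L` the reverse complement. tRNA labels
are canonicalized to a 22-name vocabulary in which the two leucine and two
serine isoacceptors are distinguished by anticodon (TAA→Leu1/UUR,
TAG→Leu2/CUN, TGA→Ser1/UCN, GCT→Ser2/AGY) or by a codon-family note in the
product text; a Leu/Ser product with neither is an error rather than a
guess. Records without exactly one control-region feature still load but
are flagged geometry-incapable, and every CR-anchored analysis refuses
them.

The built-in human record is a coordinates-only reconstruction of the
AF347015 annotation (16,568 bp): the published reference human mtDNA gene
coordinates with the historical single-base placeholder (reference
position 3107) removed, which shifts every feature downstream of it by one
base. It carries no sequence, so it supports geometry and replication
analyses but not codon counting.

## Distances from the control region

Both strand-specific transcription start points are assumed near the CR's
two 3' ends, so there are two reference bases: `h_ref`, the last base of
the CR arc walking in increasing coordinates (tRNA-Phe side), and `l_ref`,
its first base (tRNA-Pro side). The distance of a tRNA is the circular gap
from the strand's reference to the gene's coding-strand 5' base, with the
adjacent base counting as 1; on the human record this gives Phe = 1 (H)
and Pro = 1 (L), which is what forces the two-reference convention.

Actual transcription start sites are unknown for most species, so the
analyses can be repeated under hypothetical start offsets of ±150 and
±500 bp per strand. An offset is a displaced linear start point, so it
shifts each distance by a constant *without* circular re-wrapping;
distances of genes upstream of a downstream-shifted start become ≤ 0.
This choice matters: a rank test is invariant under a common shift (the
robustness the offsets are meant to probe), whereas re-wrapping the
CR-adjacent genes (distance 1) to the far end of the circle would turn
the offset analysis into a different experiment entirely.

## Codon usage

Codons are counted over the 13 protein-coding genes under translation
table 2, each CDS read in its own frame from its own 5' start (L-strand
CDS reverse-complemented first). Bases shared by the two known overlapping
gene pairs are counted once per gene, in each gene's frame. Complete stop
codons and incomplete (polyadenylation-completed) terminal codons are
excluded: no tRNA decodes them. Internal stops warn but do not abort,
since vertebrate mt annotations occasionally contain pseudo-stops. The 22
codon families (8 four-codon boxes, 14 two-codon sets) partition the 60
sense codons; the statistic passed downstream is the family's relative
frequency, so genomes of different lengths are comparable. The embedded
mtREV and JTT equilibrium amino-acid frequencies summarize mitochondrial
and nuclear proteome composition; the hydrophobic set is
{F, V, L, I, M, W, A, G, P}, giving fractions 0.626 and 0.491 (the
published rounded matrices carry ~±0.005 of version noise).

## Rank test

The Mann-Whitney statistic is U = min(U₁, U₂) with
U₁ = #{(a, b): a > b} + ½·ties, computed from rank sums. For pooled
n ≤ 25 the p-value is exact: the null distribution of the rank sum over
all C(n₁+n₂, n₁) labelings is built by dynamic programming over the
(doubled, hence integral) pooled ranks, which handles ties exactly and is
equivalent to full enumeration. The one-tailed p is the observed
direction's tail; the two-tailed p adds the reflected opposite tail.
Beyond n = 25 a tie-corrected normal approximation (no continuity
correction) is used. On the human table this gives U = 27.000, exact
one-tailed p = 0.0145, two-tailed p = 0.0292; the headline value is
two-tailed.

## Independent contrasts

Contrasts follow the standard pruning recursion on a rooted, strictly
binary tree: at a node with daughters carrying values x_i, x_j on adjusted
branches b_i, b_j, the contrast is (x_i − x_j)/√(b_i+b_j), the nodal value
the branch-weighted average, and the parent branch is extended by
b_i·b_j/(b_i+b_j). Polytomies are rejected rather than silently resolved.
Branch lengths default to 1.0 when the newick carries none, because the
composite literature tree has no rate estimates. Pairs are sign-oriented
so the usage contrast is non-negative; correlations of contrasts run
through the origin with df = n − 1 (contrasts have zero expectation and
arbitrary sign), which makes the through-origin correlation identical to
the GLS correlation under the Brownian covariance — an identity the test
suite verifies to 1e-10 against a direct matrix oracle. Rank (Spearman)
correlations of contrast data use the ordinary statistic with df = n − 2,
the convention under which such analyses are reported. Variables enter as
log10 relative usage and log10 distance; zero usage is replaced by a
0.5/total-codon pseudocount and flagged.

Families whose distance never varies across a cohort (tRNAs pinned
adjacent to the CR, e.g. Phe and Pro at distance 1) produce all-zero
distance contrasts; they are retained in pooled analyses but dropped, with
a warning, from the per-family meta-analysis, where their correlation is
undefined.

## Replication-exposure model

O_L is the midpoint of the annotated L-strand replication origin, or —
when the annotation is missing — the midpoint of the gap between tRNA-Asn
and tRNA-Cys, the cluster that hosts it in vertebrates; with neither, the
analysis refuses. O_H is the annotated H-strand origin midpoint or,
failing that, `h_ref`. L-strand synthesis proceeds in increasing
coordinates. A tRNA is "between origins" iff its reference point (coding
5' end by default; midpoint as an option) lies on the arc from O_L to O_H
in that direction; its exposure is α there and α − β elsewhere, with
α + β = L an exact identity. On the human annotation this partition
yields exactly the 13 known between-origin tRNAs against the 9 others.
Anticodon G+T is scored at two positions under both conventions — the
first two bases 5'→3' (structural 34–35) and the two bases pairing codon
positions 1–2 (structural 36–35) — with the codon-pairing convention as
the default, since those are the mutation-sensitive non-wobble sites;
both are always reported. Anticodons resolve from the annotation
qualifier first, then the built-in canonical vertebrate table, then
error.

## Synthetic cohorts

The generator's defaults are the study conditions: 47 species, 16,500 bp
circular genomes, the typical gene arrangement (or a seeded permutation of
its tRNA geometry for rearranged-order cohorts), Brownian dispersions of
0.10 log10 units per unit branch for both usage and distance, a
usage-position cross-correlation of −0.15 (the order of magnitude of the
pooled effect the analyses are designed to detect), and a deamination
gradient of 0.5 logit units of per-position G/T probability per 10 kb of
exposure with intercept −0.40, which keeps the probability near ½ across
a genome's exposure range. Trees are Yule with unit branches.

Per species, the 22 per-family log-usage values are renormalized to sum
to one and genomes are laid out on the circle: each tRNA (70 bp) at its
realized distance, nudged by the minimum needed to stay non-overlapping
(with a backward relaxation pass near the end of the coordinate range);
free gaps receive the two rRNA blocks, a point O_L near the typical
relative position, and the 13 protein-coding genes, whose codons are
drawn i.i.d. from the per-codon target distribution. Two construction
identities hold exactly and are tested: codon counting on the emitted
sequence recovers the generator's realized codon draws, and the distance
module recovers the laid-out distances. What the generator does *not*
emulate: sequence evolution along the tree (each genome's sequence is an
independent draw given its tip parameters), rRNA/CDS length variation
tied to real gene identities, tRNA secondary structure, and duplicated
control regions. Passing tests therefore validate the statistical
machinery and the geometric conventions, not annotation quirks of real
records.

## Calibration experiments

Three simulation experiments quantify the pipeline end to end, at sizes
chosen to give tight Monte-Carlo error at interactive runtimes:

* **Recovery:** 200 cohorts of 33 species with ρ = −0.4 give a mean
  through-origin contrast correlation within ±0.05 of the truth
  (the estimator's small-sample bias toward zero is ≈ 0.005 here).
* **Type-I:** 1000 null cohorts (ρ = 0) give a one-tailed rejection rate
  of 3–7% at α = 0.05, confirming the t-distribution on n − 1 df is
  calibrated for through-origin contrast correlations.
* **Gradient power:** 200 replicates, each a cohort of 10 genomes whose
  anticodons are redrawn under the 0.5-logit/10-kb gradient, pooling the
  220 exposure records per replicate. Detection (positive pooled
  correlation) exceeds 90%. The cohort is the replicate unit because a
  single 22-gene genome carries too little information at this gradient:
  the per-genome expected correlation is only ≈ 0.15 (exposure spread
  ≈ 4.4 kb against a per-gene binomial noise SD ≈ 0.7), so per-genome
  detection plateaus near 75% no matter how many replicates are run.

## Numerical choices and limitations

Exact-U enumeration switches to the normal approximation above pooled
n = 25. Correlation t statistics use the exact relation
t = r√(df/(1−r²)) with the appropriate df per mode. The Stouffer
combination is unweighted (√k denominator) by default with a
√(n−3)-weighted option, since the exact weighting of the combined
probability is conventional rather than forced. Group labels
(stable vs rearranged gene orders) are configuration inputs, not
inferred from the annotation. Multi-CR genomes are refused until the
user designates one CR feature. No multiple-testing correction is
applied anywhere, matching the analysis design the package reproduces.
The pooled contrast counts depend on cohort composition and the
equal-branch-length assumption, so they are reported, not asserted,
by the pipeline.
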