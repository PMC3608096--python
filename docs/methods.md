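# Methods

## Parametric linkage model

The disease model is the standard single-locus parametric one: a biallelic
disease locus with population allele frequency `q` (default 1e-5), a
penetrance vector `(f0, f1, f2)` = P(affected | 0/1/2 copies of the
disease allele) (default `(0, 1, 1)`, the fully penetrant autosomal
dominant regime), and recombination fraction `θ` between the disease locus
and the marker under test.  Following the fixed-θ convention for
single-point scans, the LOD compares `θ = 0` (complete linkage) against
`θ = 1/2` (free recombination); `θ` is configurable but not maximized
over.

The two-locus likelihood sums over ordered haplotype pairs per individual
(16 states: disease allele × marker allele on the paternal and maternal
chromosome).  Founders carry Hardy–Weinberg priors under linkage
equilibrium between the two loci; each parent→child transmission picks a
starting strand uniformly and recombines with probability θ; members with
known affection contribute penetrance factors; observed marker dosages
enter as indicators (missing dosages contribute nothing).  Members of
unknown affection carry no penetrance factor — the study family contains
an equivocal member, and constraining such members would fabricate
phenotype information.

### Evaluation

The likelihood is computed by Elston–Stewart peeling, implemented as
factor-graph variable elimination in reverse-topological order (children
summed out before parents).  On loop-free pedigrees this reproduces
classical nuclear-family peeling; factor widths never exceed three
genotype axes for the pedigrees considered here.  Two numerical measures
keep 13-member pedigrees with `q = 1e-5` stable:

* every intermediate factor is rescaled by its maximum, with the log of
  the scale accumulated separately (likelihood zero — an impossible
  configuration — propagates to a −inf log-likelihood rather than NaN);
* the `θ = 1/2` denominator uses the exact factorization
  L = L(disease-only) × L(marker-only), each a 4-state single-locus peel.

A full-panel scan batches markers by their unique (dosage pattern,
allele-frequency) class and peels each class once, vectorized; an
18,000-marker exome reduces to a few thousand classes, so a scan takes
well under a second.  The brute-force enumerator over all ordered genotype
configurations (in the test suite) is the independent oracle; peeling
matches it to better than 1e-9 in log space over randomized pedigrees,
dosages, penetrance vectors and θ values.

Markers whose pattern has zero likelihood at the test θ but positive
likelihood at θ = 1/2 are obligate recombinants (LOD −∞); they are
dropped from the track (a finite-LOD track is what hot-spot clustering
consumes, and −∞ markers are simply maximal evidence against linkage).
Patterns impossible at every θ are Mendelian-inconsistent and are also
excluded, with a warning; the pipeline additionally pre-filters markers
flagged by the explicit Mendelian check.

### Marker allele frequencies

Scan inputs rarely carry trustworthy frequencies, so they are estimated
from genotyped founders when at least two are genotyped:
`p = (Σ dosage + ½) / (2n + 1)` (a half-count keeps the estimate strictly
inside (0, 1), which the founder priors require); otherwise 0.5.  For a
perfectly co-segregating marker the founder terms cancel between numerator
and denominator, so the LOD of the true peak does not depend on this
choice (the relabeling invariance `d → 2−d, p → 1−p` is tested).

### QC boundary

Genotype QC keeps a marker only when every genotyped subject has depth
≥ 10 and GQ ≥ 30 (inclusive boundary; a strict mode with exclusive
comparisons is available).  Sex chromosomes are excluded from linkage
entirely — no X-linked model is implemented.

### Hot spots

Markers with LOD ≥ 1.5 are clustered greedily per chromosome, merging
neighbours separated by ≤ 10 Mb and keeping clusters with ≥ 2 markers by
default.  The thresholds are configurable; the 10 Mb gap and 2-marker
minimum reflect that real exome scans produce clustered peaks (linked
markers share the disease haplotype) and that the smallest interesting
cluster observed in practice has two members.  **Caveat for synthetic
data:** the generator simulates linkage equilibrium with only the causal
marker linked to disease, so the true peak has no linked neighbours and is
a single marker unless a chance co-segregator lands within the gap.
End-to-end recovery studies on synthetic families therefore run with
`min_markers = 1`; this is a property of the generator's (deliberate)
LD-free design, not a recommendation for real data.

## CNV calling and co-segregation

Depth normalization: per-sample library-size factors (total exon depth
scaled to the across-sample mean) are divided out; the per-exon baseline
is the across-sample median of normalized depths; exons with baseline
below 10 reads are masked (never infinite ratios).  Ratios are
`log2(normalized depth / baseline)`.

Calling: exons are binned into 20 equal-occupancy baseline-depth bins
(bins under 10 exons merge with a neighbour); within each bin the ratio
scale is estimated robustly as MAD × 1.4826 around the bin median (if the
MAD degenerates to zero the bin standard deviation is used; if that is
also zero all z-scores are zero).  The two-sided normal tail of
`z = (ratio − median) / scale` is the call p-value; a call is gain/loss
iff `p < α` (strictly) with the matching sign, α = 0.05 by default.  This
is a deliberately simplified per-exon depth-ratio test: the contribution
here is the co-segregation scan, which needs only a 3-state exon × sample
matrix, and any external caller producing such a matrix can be plugged in.
Sex-chromosome exons are retained (CNV is descriptive, unlike the linkage
model).

Co-segregation: per exon the 3×2 table of state (gain/normal/loss) by
group (affected/unaffected; arbitrary two-group partitions are supported
for internal validation) is scored with the exact conditional test with
both margins fixed: the p-value sums the multivariate hypergeometric
probabilities of every table with the observed margins whose probability
does not exceed the observed table's (two-sided by probability ordering).
The enumeration runs in exact rational arithmetic, so probability ties are
decided exactly and no tie tolerance is needed; p-values are cached by
table, which makes permutation studies cheap.  A zero-total table scores
p = 1 by convention.  With 4 + 4 samples the smallest attainable p is
2/70 ≈ 0.0286, and the discreteness makes the test conservative: under
phenotype permutation the fraction of exons at p ≤ 0.05 is far below 0.05
(the calibration study checks the one-sided bound `≤ α + 3·SE`, the only
direction a conservative exact test can be held to).

## SNV funnel

Filters are pure functions (survivors are always a subset of the input,
and qc/effect/segregation commute):

* **QC** — every sequenced member's genotype at depth ≥ 10 and GQ ≥ 30
  (same boundary semantics as linkage); optional autosome restriction.
* **Known-variant filter** — `annotate_only` by default: database ids and
  population frequencies are carried along but do not drop variants,
  because the decisive family filter is co-segregation and known common
  variants demonstrably survive it in practice; `drop_known` (id present
  or frequency above a cutoff) is available for the classical
  novelty-first ordering.
* **Effect** — keeps nonsynonymous, stopgain, stoploss, frameshift,
  nonframeshift and splicing; synonymous, "other" and unannotated
  variants are dropped (the last with a warning).
* **Segregation** — dominant rule: dosage ≥ 1 in every sequenced affected
  member (hom-alt carriers stay consistent with dominance) and dosage 0 in
  every sequenced unaffected member.  A missing genotype in either group
  fails the variant — conservative, because a false negative can be
  recovered by relaxing QC, while a false positive propagates.  Members
  with unknown affection are not constrained.
* **Hot-spot intersection** — candidates must fall inside a hot spot
  (1-based inclusive endpoints) and are annotated with the containing hot
  spot's maximum LOD; the intersection can be disabled so the
  unintersected co-segregating set remains reportable as its own track.

Annotation (gene, effect, HGVS, database id, population frequency) is
consumed from a sidecar table keyed by (chrom, pos, ref, alt); computing
annotation is out of scope.

## Synthetic generator

`famphase.simulate` emulates the study conditions: a 13-member,
3-generation pedigree (8 sequenced: 4 affected including one founder and
4 unaffected; one member of equivocal status; a married-in spouse and
three grandchildren who extend the 11-subject array panel), 18,000
autosomal markers with allele frequencies uniform on (0.05, 0.95), mean
depth 45×, 5,000 capture targets, and five implanted non-co-segregating
CNV loci echoing the kinds of loci such scans find (a shared locus with
reciprocal gain/loss carriers plus scattered single-carrier events).

Design choices that matter:

* **Gene dropping.**  Founders draw haplotypes under HWE and linkage
  equilibrium; children inherit with free recombination between markers.
  The causal allele occupies one haplotype of the affected founder, is
  private to the family, and is transmitted so carriers coincide with
  affected members (members of unknown affection inherit it at random) —
  the deterministic counterpart of full penetrance.  Configurations that
  would require an affected member without a carrier parent are rejected.
  Markers are mutually unlinked because the analysis is strictly
  single-point; this simplifies the analytic oracle (the causal marker's
  LOD equals the pedigree's analytic maximum, (I−1)·log10 2 for I
  phase-unknown informative meioses) at the cost of realistic LD — see
  the hot-spot caveat above.
* **Variant-site depth** is `10 + NB(mean − 10, size 30)` per genotype:
  genotype calls presuppose minimally adequate coverage, so the DP
  distribution at called sites is bounded away from zero even though raw
  target coverage is not (the exon depth matrix, by contrast, uses an
  untruncated negative binomial and does produce sub-threshold exons).
* **Exon depth** is simulated at read-count level: reads ≈ NB(mean =
  depth × length/100 × size factor × capture factor × CN/2, size 400),
  depth = reads × 100 / length, with target lengths lognormal around
  ~300 bp and capture efficiency lognormal (σ = 0.5 by default; the CNV
  recovery study sets σ = 0 so implanted events sit exactly at the
  nominal 45× the study design states).  Depth is linear in copy number
  by construction — the premise that makes exome CNV calling possible.
* **Genotype errors** flip a dosage to a uniformly chosen different value
  at the configured rate; erroneous genotypes carry GQ ~ U(5, 40) while
  correct ones carry GQ 99, so the GQ filter is actually exercised.

What the generator does **not** model: linkage disequilibrium and shared
IBD tracts (hence single-marker true peaks), GC and mappability bias,
multi-allelic sites, X-linked inheritance, realistic gene annotation
(genes are 1 Mb position buckets), and read-level artifacts.  Passing
tests therefore demonstrate the statistical machinery is correct under the
stated model, not that the pipeline is robust to every real-data pathology.

## Validation studies and problem sizes

The replicate studies (`famphase.experiments`) use: 200 randomized
pedigrees for the peeling-vs-enumeration oracle; 100 synthetic families
each for error-free and 0.2%-error recovery (recovery must be 100%
error-free; ≥ 95% with errors, since a causal-genotype error either fails
QC or breaks the segregation pattern — both expected, at rate
1 − 0.998⁸ ≈ 1.6%); 200 replicates × 3 exons for each implanted CNV
class; 1,000 phenotype permutations for the CNV null; and 5,000
single-marker replicates for the unlinked-marker LOD null (the larger
size keeps the Monte Carlo error of the ~0.7% exceedance rate well below
the 1% bound being checked).  Seeds derive from a single base seed
throughout.

## Known limitations

Single-point linkage only (no multipoint, no haplotype reconstruction);
autosomal models only; biallelic markers only; the CNV caller is
exon-granular with no breakpoint refinement or GC correction; pedigrees
with loops are not supported by the peeling order (the elimination engine
would still be exact but factor widths could grow).
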