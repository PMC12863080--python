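# Methods

## Core genome and signed permutations

A species is a set of ≥ 2 (in practice > 5) complete genomes with
ortholog-family assignments taken as given (ortholog inference is
upstream of this package). A family is **core** when it occurs in at
least a fraction `freq` (default 0.90, inclusive ≥) of the genomes and
is single-copy in every genome where it occurs; a family duplicated in
*any* genome is excluded outright, since a paralogous copy makes gene
order ambiguous. The threshold is exposed because conventions differ
on whether "90% frequency" is strict or inclusive.

Each genome is then reduced to its **signed circular permutation** of
core families: gene order around the chromosome with a sign per gene
(strand). Accessory genes are skipped but counted per inter-core
interval, so blocks can later report their total gene content.
Coordinates are 1-based inclusive on sequences; permutation and window
indices are 0-based internally. Genes wrapping the circular origin
(end < start) are rejected: this keeps midpoint arithmetic simple and
the synthetic generator never emits them.

## Block finding

Against a reference, the query's shared core genes become arrays
`(pos, sign)`: reference index and relative strand. The adjacency
j → j+1 is **conserved** iff `sign[j] == sign[j+1]` and
`pos[j+1] == (pos[j] + sign[j]) mod m`; this single rule covers both
forward runs and fully reversed, strand-flipped runs. Blocks are the
maximal runs between non-conserved adjacencies (breakpoints), with the
last/first elements adjacent on both genomes (circular). Runs of one
core gene are discarded as possible orthology errors but counted.
Circularity is what makes one inversion yield 2 blocks and one
interior translocation 3.

Properties that follow (and are property-tested): the retained-block
and singleton counts are symmetric in the pair; core genes partition
exactly into blocks plus singletons; and the conserved-adjacency set
is invariant under whole-genome reversal of the query. That last
invariance means breakpoint counting cannot distinguish a
reverse-complement deposit from the forward assembly — so
canonicalization is driven by the backbone instead: if the largest
block reads reverse, the query's global strand is flipped before
classification. Without this, an assembly deposited on the opposite
strand would misclassify every translocation as an inversion. On
linear genomes (flag) the orientation with fewer breakpoints is
additionally preferred, since there the counts can genuinely differ.

Classification: the largest block (ties: more total genes, then
smaller reference start) is the **backbone**, the unrearranged frame.
Every other block is an **inversion** if its order is reversed
relative to the reference, else a **translocation**. Order is primary:
a reversed block whose genes mostly kept their annotated strand is
still called an inversion, with a warning (strand annotations are
noisier than order). The reference genome for a species is the one
minimizing the average retained-block count over all other genomes
(ties: lexicographically smallest id), and its trivial self-comparison
is excluded from species means. Blocks whose orientation-normalized
family tuple occurs more than twice across the pooled pairs are
dropped before positional and enrichment analyses, so one ancestral
event shared by several strains is not counted repeatedly.

## Ori/Ter from GC skew

Leading strands are G-rich, so the windowed skew S = (G − C)/(G + C)
(non-overlapping 1,000-bp windows; a trailing partial window is
dropped; windows with no G or C contribute 0) switches sign at the
replication origin and terminus. Ori and Ter are the global minimum
and maximum of the cumulative skew curve. Two numerical choices:

- Windows are non-overlapping rather than stride-1 sliding: at 1-kb
  resolution the cumulative curve is indistinguishable and the cost is
  a fraction. Stride is exposed via the window parameter.
- Extrema are located on the **mean-centered** cumulative curve (the
  raw cumulative sum is also reported). A nonzero genome-wide mean
  skew adds a linear drift to the raw curve whose extrema then depend
  on where the assembly happens to start; centering makes the located
  Ori/Ter equivariant under rotation of the assembly start. With
  balanced replichores the curves have the same extrema.

A profile is flagged **ambiguous** — and its genome excluded from
positional analysis — when a secondary valley (or peak) of the
centered curve has prominence ≥ 20% of the curve range at least 5% of
the genome away from the global one, or when the global extremum is
not a prominent feature at all (e.g. an unskewed random walk). Peak
finding runs on a tiled copy of the curve because it is periodic;
otherwise extrema near the assembly start lose prominence to boundary
effects. The published analyses this mirrors judged ambiguity by eye;
the prominence rule is a stated, reproducible stand-in, and both
thresholds are parameters.

Each rearranged block midpoint is mapped to the replichore containing
it and scaled by that replichore's length: d = 0 at Ori, 1 at Ter.
Pooled distances (after dedup, excluding single-block genomes and
ambiguous profiles) are tested against the neutral value 0.5 with a
two-sided one-sample Wilcoxon signed-rank test; the direction (Ori vs
Ter) is reported from the median. The neutral reference is the
constant 0.5 rather than a genome-specific null: under uniform
placement, d is uniform on each replichore regardless of arc lengths.

## Blocks → events calibration and B_cs

Observed block counts are converted to event estimates by simulation:
k events are applied to the identity permutation of size C — each an
inversion with probability 0.5, else a translocation to a uniformly
chosen other adjacency; segment lengths uniform on [2, max(3, C/10)]
genes (a 1-gene segment would be a discarded singleton) — and the mean
retained-block count per k is fitted with a least-squares quadratic.
The event mix and segment-length law are not identifiable from block
counts alone and are exposed as configuration; calibration is run per
species at its own C. The translocation operator preserves the
coordinate frame of the unmoved genes, so simulated breakpoints carry
no positional artifact (an earlier formulation that rotated the
permutation to the excision point systematically aligned breakpoints
with the origin).

The fitted curve is monotone over the grid but **discontinuous at
zero** in truth: an identity genome has 1 block, while a single event
already produces 2–3, so the mean jumps from 1 to ≈ 2.5 between k = 0
and k = 1 and the fitted intercept settles near 0.4 rather than 1.
The inversion of the map therefore handles B = 1 explicitly (N = 0, no
rearrangement) and otherwise takes the smallest non-negative real root
(parsimony); beyond the calibrated range it extrapolates linearly with
a warning. Planted-event recovery under these defaults: median
predicted k within ±1 for k ≤ 5 and within ~5% for k ≤ 10 at C = 500
(saturation begins when breakpoints start to coalesce, k ≳ C/10).

The rate is B_cs = N / (C · S · L): predicted events per substitution,
normalized by core-genome size and alignment length. S is the count of
alignment columns where both genomes carry unambiguous A/C/G/T and
differ; gap and ambiguity columns are excluded. An external per-site
distance matrix (square PHYLIP, e.g. maximum-likelihood distances) can
replace raw counts via S = distance × L, and a Jukes–Cantor correction
helper is provided (off by default — the formula's S is a count).

## COG enrichment

For each COG (one-letter category or individual id) a 2×2 table
compares its count among the genes of rearranged blocks — core *and*
accessory genes inside the block spans — against its count among all
genes of all genomes. Following the source layout, the genome-wide
column **includes** the block genes; a `disjoint` flag subtracts them
for the orthodox disjoint table. Excluded from the block side:
single-block genomes, backbone blocks, and >2-occurrence duplicates.
Unannotated genes count toward the "other" cells but are not
themselves tested. Tests are Pearson χ² (df = 1, no continuity
correction; expected cells < 5 flag the result rather than switching
to Fisher), corrected by Benjamini–Hochberg within each scope
(translocations, inversions, or all), and enrichment additionally
requires the block frequency to exceed the genome-wide frequency.

## Statistical kernel

The primitives are implemented in-package so small-sample behaviour is
explicit and under test; scipy supplies only distribution tails:

- **Wilcoxon signed-rank**: zero differences discarded (classic
  convention, not Pratt); exact null by subset-sum DP for n ≤ 25
  without ties; otherwise normal approximation with tie and continuity
  corrections. The approximation tracks the exact branch to within
  ~10% where p > 0.05 and degrades in the far tail, as expected.
- **Wilcoxon rank-sum**: mid-ranks; exact null by enumeration when the
  smaller group has ≤ 8 observations (and the combination count is
  tractable); otherwise normal approximation with tie correction.
- **Spearman**: Pearson on mid-ranks, t-approximation with n − 2 df;
  zero rank variance returns a flagged undefined result.
- **χ² 2×2**: Pearson statistic; a zero margin returns p = 1 flagged.
- **BH**: step-up with enforced monotonicity, checked against the
  literal definition.
- **Quadratic fit**: least squares on [1, x, x²] via `numpy.linalg.lstsq`;
  fewer than three distinct x values is an error.

All four tests are verified against independent oracles (enumeration,
the closed 2×2 formula, scipy) and for null calibration: p-values
under the null are uniform with KS statistic ≲ 0.03 at 2,500
replicates (2,500 rather than 1,000 so the KS statistic's own sampling
noise stays well inside the 0.05 tolerance being checked).

## Synthetic species generator

`make_species` emulates the inputs the analysis assumes:

- **Genealogy**: a star — every genome rearranged and mutated
  independently from one ancestor. Clonal structure within species is
  nuisance for these analyses, and a star keeps per-branch truth
  independent, so every planted event belongs to exactly one genome.
- **Gene content**: C core families (default 100) in ancestral order,
  with Poisson(1) accessory genes per inter-core interval shared
  across genomes; genes are laid out evenly (900-bp genes on a 1-Mb
  default chromosome).
- **Rearrangements**: Poisson(1.5) events per branch, inversions and
  translocations with the same operators used by the calibration
  simulations, applied to core units with their interval accessory
  genes travelling along. Explicit event lists can override the draw
  per genome (used to plant worked examples and clean references).
- **Substitutions**: Poisson(rate × L) positions per branch, placed
  without replacement on a random ancestral alignment (default
  300 nt per core gene, 0.002/site/branch), so pairwise truth is exact
  up to logged between-branch collisions.
- **Replichores**: sequences are built position-by-position with a G
  excess of δ (default 0.2) on the leading arc between planted Ori and
  Ter (defaults: positions 0 and L/2, i.e. balanced replichores).
  The sequence is generated independently of the gene layout.
- **COG labels**: ancestral draws from a 10-category alphabet plus
  "unannotated" (46%); the mobilome category X (base 3%) is drawn at a
  5-fold boosted rate for accessory genes inside rearranged spans —
  all units outside the backbone run relative to the ancestor — and X
  genes carry the transposase flag.

What the generator does **not** emulate — hence what green tests do
not certify about real data: indels and recombination/HGT on the
alignment, gene gain/loss (accessory content is shared), orthology
errors beyond what the singleton filter absorbs, assembly errors,
multi-chromosome or linear replicons, skew noise from mutational
hotspots, and correlated event placement. The block-count saturation
beyond k ≈ C/10 is a property of the statistic itself and is shared
with real data.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen to
give each stochastic check clear resolution: oracle equivalence on
5,000 random permutations of ≤ 12 core genes; calibration at C = 500
over k = 0..20 with 100 replicates and 200 recovery trials per k;
neutrality with 10,000 uniform midpoints and 1,000 replicate tests of
n = 50; Ori/Ter recovery on twenty 1-Mb sequences; enrichment on an
8-genome species with 150 core families. The full suite runs in well
under a minute of CPU apart from the acceptance-style simulations.

## Known limitations

- Breakpoint runs, not a rearrangement scenario: the package counts
  and classifies blocks; it does not reconstruct event histories
  (no DCJ distance or ancestral ordering).
- The inversion/translocation call is local per block; a transposition
  of a reversed segment is called an inversion.
- The calibration assumes the simulated event mix; if a species'
  true mix differs (e.g. inversion-dominated), N is biased by the
  2-vs-3 blocks-per-event difference, bounded by ~30%.
- The contingency layout double-counts block genes in the genome-wide
  column by design (fidelity to the source method); use `disjoint`
  for the orthodox test.
- Multi-chromosome genomes are out of scope; linear chromosomes are
  supported for block finding only, and excluded from Ori/Ter work.
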