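# Methods

`pansynkit` implements the analysis layer of a gene-based pan-genome study of
chromosome-level plant assemblies: gene-family classification with orthogroup
correction, pan/core rarefaction, windowed synteny diversity, cross-accession
structural-variant (SV) merging, and centromeric tandem-repeat quantification
with depth-based completeness estimation. Every stage is exercised on
synthetic inputs with known ground truth; this note records the models, the
parameters that matter, and the design choices made where the design was open.

## Gene-family classification

The pan-genome matrix is a families × accessions table of non-negative gene
counts; a family is *present* in an accession when its count is ≥ 1. With `n`
accessions and presence count `m_f`, categories follow presence-count rules
with a softcore fraction `t` (default 0.90):

| category    | rule                | at n = 69 |
|-------------|---------------------|-----------|
| core        | `m_f = n`           | 69        |
| softcore    | `t·n < m_f < n`     | 63–68     |
| dispensable | `2 ≤ m_f ≤ ⌊bound⌋` | 2–62      |
| private     | `m_f = 1`           | 1         |

The softcore inequality is **strict** and evaluated in exact rational
arithmetic (`Fraction`), because `0.9 * n` is not always representable in
binary floating point at integer boundaries (e.g. n = 60). A consequence
worth knowing: at n = 10 the softcore range `9.0 < m < 10` contains no
integer, so the generator refuses a configuration that requests softcore
families at n = 10. Families absent everywhere are labelled `absent` and
excluded from category counts.

Per-accession composition is **gene-level**, not family-level: each
accession's fraction per category uses its gene counts, so multi-copy core
families weigh more. This is why core families (~60% of the catalogue)
constitute ~80–87% of any individual genome's genes — rare families
contribute few genes each.

## Orthogroup correction

Automated clustering over-splits some families and gene annotation
differences create artificial presence/absence:

* **Fusion** — a homology hit qualifies when query and target coverage are
  both ≥ 0.95 *and* the pair is a reciprocal best hit (highest score in both
  directions, per target accession; score ties break lexicographically on
  gene id for determinism). Qualifying hits joining different families merge
  them by transitive closure (union–find). The operation never increases the
  family count, is idempotent, and is independent of hit order; the merged
  family keeps the lexicographically smallest member id.
* **Split–merge flagging** — a family is flagged when some accession holds
  two genes *adjacent in that accession's genome gene order* whose alignments
  onto the family representative each cover < 95% of it individually but
  ≥ 95% jointly (union of covered target positions). The representative is
  the member from a designated reference accession when present, otherwise
  the longest member (ties on gene id). Flagging runs after fusion.
  Private families cannot be flagged under this rule: their longest member
  would be one of the adjacent pair and covers itself fully. Flagging them
  requires an external reference gene set, which is out of scope here, so
  the generator plants split–merge artifacts only in families present in at
  least two accessions.

## Rarefaction

For subset size `k` drawn from `n` accessions, closed forms give the exact
expectations

```
E[pan(k)]  = Σ_f [ 1 − C(n − m_f, k) / C(n, k) ]
E[core(k)] = Σ_f C(m_f, k) / C(n, k)
```

computed with exact integer binomials (`math.comb`). The Monte-Carlo curve
draws, per `k`, `R` uniform accession subsets without replacement (subsets
may repeat across replicates; default R = 2,000, sizes 2..n−2) and reports
mean and standard deviation of pan (families present in ≥ 1 sampled
accession) and core (present in all sampled). Sampling is a single
seeded generator; the implementation evaluates all replicates of a given `k`
with one boolean matrix product. The closed form is the test oracle: the MC
mean must lie within `4·sd/√R` of it for every `k`.

## Windowed synteny diversity

Each accession's whole-genome-alignment blocks against the reference are
projected to a per-position indicator `s_i(p)`: 1 under SYN blocks, 0 under
rearranged (INV/TRANS/DUP/…) or unaligned (NOTAL) blocks or no coverage.
Rearranged-but-aligned sequence deliberately counts as non-syntenic: the
statistic is designed to highlight rearrangements. Two accessions are
jointly syntenic at `p` iff both are syntenic *to the reference* there
(reference-projection approximation; no all-vs-all alignment is computed).

For a window `w` over `n` accessions:

```
π_syn(w) = 2/(n(n−1)) · Σ_{i<j} (1/|w|) · Σ_{p∈w} (1 − s_i(p)·s_j(p))
```

0 means every pair is colinear across the window, 1 means no pair shares a
syntenic position. Pairs are weighted position-wise (not by aligned length),
which makes the pair sum collapse to `C(m(p), 2)` where `m(p)` is the number
of syntenic accessions at `p`. The implementation sweeps all interval
endpoints once per chromosome into segments of constant `m`, builds prefix
sums, and answers each window exactly — it equals the per-position
definition to machine precision, which the test suite checks against a
brute-force per-position oracle.

Windows are anchored at position 1 and advance by the step (defaults
100 kb / 50 kb); the last window is truncated at the chromosome end and
kept with its true length. Genome fractions below/above the 0.2 / 0.5
diversity thresholds are window-length-weighted. Pairwise colinearity
restricted to an arm mask (centromeres excluded) gives an accession ×
accession matrix whose within/between-group means summarise population
structure.

One subtlety: π_syn is *not* monotone under duplicating an accession. A
duplicate of a fully syntenic accession can only lower it, but duplicating a
poorly aligned accession adds pairs less colinear than average and raises it.
The test suite pins the provable direction only.

## SV merging

SURVIVOR-style single-linkage clustering in two size tiers, following the
parameter strings `1000 1 1 0 0 1` (20 bp–10 kb) and `20000 1 1 0 0 1`
(> 10 kb): two records link iff same type, same chromosome, and **both**
breakpoints agree within `max_dist` (|Δstart| ≤ d and |Δend| ≤ d). The six
parameters are read as (max distance, min callers, type match, strand match
off, no distance estimate, min size 1); applying the distance to start and
end independently is the closest documented semantics of the merge tool
being emulated. Cluster representatives take the per-coordinate median of
members (robust, deterministic); support counts distinct accessions.
Records are canonically sorted before clustering, so the result is
independent of input order, and `max_dist = 0` degenerates to
exact-coordinate deduplication (tested against a hash-grouping oracle).

## Centromere sizing

Centromeres of *A. thaliana* are megabase tandem arrays of a ~178-bp
satellite monomer; telomeres repeat a 7-bp unit. Two measurements are
combined per accession:

* **Assembled length** — the assembly is scanned for motif matches within
  edit distance ≤ `max_divergence × |motif|` (default 20%), greedily tiled
  left-to-right without overlap, on both strands. Long motifs (≥ 20 bp) use
  banded edit distance (edlib) behind an exact 10-mer seed prefilter — a
  copy diverged at rate d misses all ⌊178/10⌋ seeds with probability
  ≈ (1−(1−d)¹⁰)¹⁷, negligible below ~15% — with a local slide-right
  refinement so exact copies anchor at their true start. Short motifs use a
  vectorised substitution-only scan (indels are immaterial at 7 bp).
  Same-strand hit runs separated by ≤ one motif length merge into arrays;
  isolated singletons are dropped (`min_copies`, default 2 — chance 7-mer
  near-matches otherwise masquerade as arrays). Annotation operates on the
  assembly directly; no read mapper is involved.
* **Depth estimate** — genomic repeat bp = (Σ per-base depth piled on a
  4-copy motif concatemer) / (genome mean depth). The genome mean is taken
  over positions *outside* annotated arrays: when arrays are partially
  assembled, reads from missing copies pile onto the assembled ones and
  would otherwise inflate the denominator (circularity).

`completeness = assembled / estimated`; values > 1 are legal (over-assembly)
and flagged, and the same ratio applied to assembly size vs estimated genome
size measures whole-genome completeness. Per-chromosome estimates are
apportioned from the single genome-wide concatemer signal proportionally to
each chromosome's assembled array length — the signal itself carries no
chromosome labels, so any split is a modelling choice; proportionality is
the neutral one. Size correlations are product-moment Pearson r with
two-sided p from the t transform; zero-variance columns report NaN rather
than erroring.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes — not
sequences of real genes or satellite biology. One global seed feeds four
independent substreams (`numpy SeedSequence.spawn`: presence/absence,
homology, synteny, repeats/depth), so components are reproducible in
isolation and all outputs are byte-identical across runs for a fixed seed.

**Presence/absence** (`simulate_pav`). Category counts are one multinomial
draw from the configured proportions (default 0.60/0.05/0.17/0.18, the
split observed in the 69-accession collection). Presence counts are uniform
over each category's legal range — softcore over 63–68, dispensable over
2–62 at n = 69 — a maximum-entropy default, since only the range bounds are
established; the within-class distribution is not, and this choice is
flagged as unverified. Member accessions are uniform subsets. Each present
accession gets one gene (two for the split accession of a split–merge
family); gene lengths are ~0.9–3 kb and genes are laid out in random order
with 500 bp spacing, so genome gene order is defined for adjacency tests.

**Planted artifacts.** A configurable fraction of families (default 5%) is
over-split into two orthogroup rows with ≥ 95%-coverage reciprocal best hits
across them (fusion must merge them); another 5% get split gene models — two
adjacent genes covering disjoint portions of the representative, < 95%
individually and ≥ 95% jointly (flagging must catch them, and only them).
Near-miss hits (sub-threshold coverage, or high coverage but one-directional)
are planted as negative controls. Score bands are disjoint by construction
so reciprocal-best relations are unambiguous.

**Synteny** (`simulate_synteny`). Realistic *A. thaliana* coordinates
(5 chromosomes, 18.6–30.4 Mb, 3–4 Mb centromere spans) — pure interval
arithmetic, no sequence. Chromosome arms are SYN except: one inversion of
configurable size (default 1.2 Mb) shared by a configurable subset (default
8 accessions) at a fixed pericentromeric locus with ≤ 2 kb per-accession
breakpoint jitter; private arm inversions (Poisson, default 0.1 per genome —
seven arm inversions across 69 genomes in the motivating data — sized
1–2.5 Mb); and Poisson indels (default 20 per genome, 20 bp–10 kb), which
live below block resolution and are emitted as SV records only. Centromere
spans are scrambled per accession into 3–8 segments of NOTAL/INV/TRANS/DUP,
producing the high-diversity centromeric signal. Every accession's blocks
tile the reference exactly.

**Repeats and depth** (`simulate_repeats_and_depth`). Sequence scale is
deliberately reduced so per-base tracks stay desk-sized: per chromosome,
telomere array + 15 kb arm + centromeric array + arm + telomere array, with
50–150 motif copies per centromere (i.e. ~9–27 kb arrays standing in for the
10–22 Mb range of real centromere complements) and i.i.d. per-copy
substitutions at 5% (exercises approximate matching without modelling
satellite evolution). Genome size = base + Σ repeat length + Gaussian noise
(absorbed into the last arm). The noise sd (default 4,500 bp) was derived
from the generator's repeat-length variance — Var(repeat) =
5·178²·(100²/12), so sd_noise = sd_repeat·√(1/0.93²−1) — to reproduce the
observed strength of the assembly-size/centromere correlation (r = 0.93);
with zero noise the correlation is exactly 1. Depth tracks are Poisson
around 30× (the depth used throughout the repeat-estimation analyses); the
concatemer track has per-base mean `depth_mean · L_repeat / 712`, so its
sum is `depth_mean · L_repeat` in expectation, exact in noise-free mode.
A truncation factor writes only that fraction of each array's copies into
the assembly while depth still reflects the full array — planting a known
completeness.

What the generator does **not** emulate: read-level noise (no FASTQ),
sequence content of genes, higher-order repeat structure of real satellite
arrays, segregating heterozygosity, or any correlation between gene
categories and genomic position. Passing tests therefore demonstrate the
*algorithms* are correct against the stated models, not that real data meet
those models.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive everywhere (GFF3/SyRI convention);
  half-open arithmetic is confined to window internals.
* Unknown SyRI annotation codes skip with a warning (dialect drift between
  versions); alignment-level rows (`SYNAL` etc.) are silently ignored.
* Depth files read back dense; missing positions are depth 0; non-monotone
  positions are a format error.
* π_syn is clamped to [0, 1] against float round-off; windows beyond the
  chromosome end are truncated.
* Empty SV input yields an empty summary; records outside a tier's size
  bounds are skipped with a warning pointing at the other tier.
* Phylip export truncates accession names to 10 characters and errors on
  collision rather than silently renaming.

## Problem sizes used by tests and the acceptance script

Test and acceptance runs use 69 accessions × 5,000 families for parameter
recovery, 10 × 200 matrices for exhaustive rarefaction enumeration, 50
random 100 kb instances for the π_syn oracle, 1,000 planted cases for
fusion, full 69-accession genome-wide synteny at 100 kb/50 kb windows, and
100 Poisson replicates at 30× for depth estimation; the pipeline demo runs
~10–20 accessions end to end. These sizes were chosen so the whole suite
completes in well under a minute of compute per stage while every check
retains its statistical power.

## Known limitations

* Joint synteny is approximated through the reference projection; a pair
  rearranged identically relative to the reference still counts as
  non-syntenic at those positions.
* Split–merge detection is blind to private families (see above) and to
  splits into ≥ 3 gene models unless consecutive pairs already satisfy the
  joint-coverage rule.
* The SV merger clusters single-linkage; long chains of pairwise-close
  records can merge records farther apart than `max_dist`, as in the tool it
  emulates.
* Repeat annotation estimates copies as array length / motif length; it does
  not segment arrays into individual diverged monomers.
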