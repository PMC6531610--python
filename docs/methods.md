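# Methods

This note documents the models behind `invscout`, the defaults and why they
were chosen, what the simulators do and do not emulate, and the numerical
conventions. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate model and the reflection map

All coordinates are 0-based half-open internally; SAM/VCF export is 1-based.
A donor genome differs from its reference by a set of non-overlapping
inversions. A donor position `p` inside an inversion `[s, e)` maps to the
reference as `p ↦ s + e − 1 − p` with a strand flip; outside, it maps to
itself. The map is an involution, which the property tests exploit: mapping
donor → reference → donor returns the original position and strand.

Alignments are computed analytically from this map — no base-level read
simulation, error model or aligner is involved. This is deliberate: both
callers consume only positions, strands and segment structure, so the
simulation models exactly the evidence they use. Consequences: simulated
breakpoint coordinates are exact (real aligners add clipping slop at
LCR-homology boundaries, absorbed here by the long-read caller's 100 bp
junction tolerance and the `min_segment_bp` floor); mapping ambiguity
inside repeats is represented only through the `mapq` field and the
caller's mapq ≥ 20 filter, not emulated; and per-base errors are
substitutions only, with no indels, since orientation/position evidence is
insensitive to them. Passing tests therefore demonstrate the correctness of
the calling logic under the stated evidence model, not robustness to
aligner artifacts.

## Synthetic scenarios

The default scenario scales the discovery setting down by 10×: a 1 Mb
chromosome; a pair of inverted 20 kb low-copy repeats at 98% identity
separated by 360 kb; an NAHR-mediated inversion with one breakpoint drawn
inside each repeat copy (≈390 kb span); an FR paired-end library at 30×
with 350 ± 35 bp inserts and 100 bp reads; and 20 kb long reads at 6× —
the two library designs of the original discovery (the insert-size standard
deviation is not documented for the real library; 10% of the mean is used).
Pair count is `coverage · L / (2 · read_len)`. Reads overlapping a
breakpoint are emitted as clipped records carrying a spanning flag rather
than dropped: the short-read caller must tolerate them (it ignores them;
the junction evidence belongs to the long reads).

The pedigree template is a three-generation autosomal-dominant family with
four sequenced affected members in three generation-III sibships and
ungenotyped founders. The family variant table plants four classes:
`linked_unique` (ride the disease haplotype; absent from panels and
controls), `linked_shared` (ride the haplotype; panel MAF drawn
log-uniformly in [10⁻⁴, 9·10⁻³]; present in ≥1 genotyped control),
`linked_noncoseg` (heterozygous in all sequenced affecteds but also carried
by a genotyped married-in founder — Mendelian-safe by construction — so
they fail co-segregation in the wider family), and `offlocus`
(gene-dropped through the pedigree independently of affection). The default
counts 4/34/41/100 make the filter cascade reproduce the published funnel
exactly: 79 shared rare heterozygous variants in the linked locus, 38
co-segregating, 4 unique to the family. The third class is this package's
addition; without it the in-locus stage would start at 38 rather than 79,
because the published 79 includes variants later excluded by validation and
segregation.

The case/control generator follows the published power-simulation design:
a 3545 bp target, 40% causal and 10% protective rare variants, maximal
odds ratio 5. Unstated choices, fixed once: one variant per ~100 bp (35
variants), MAFs log-uniform in [10⁻⁴, 9·10⁻³], per-variant log-OR
proportional to |log₁₀ MAF| so the rarest effect variant attains the
maximal OR, a logistic disease model with 10% baseline prevalence, and
case/control quotas filled by rejection sampling (which preserves odds
ratios under case-control ascertainment). Under these conditions the
acceptance script measures ~88% rejection at α = 0.05 for the full
558 + 755 design — consistent with the published claim that cohorts above
~925 individuals reach 80% power.

## Short-read caller

"Markedly different from the expected insert size" is operationalized as
outside median ± k·(1.4826·MAD) of |TLEN| over FR pairs, k = 5 by default —
robust to the discordant tail and configurable. Inversion evidence is
orientation discordance only; distance-discordant FR pairs are never
clustered, which is why inversion-free libraries produce zero calls at any
coverage. Clusters are single-linkage on the leftmost-mate coordinate with
gap ≤ the concordance upper bound. A `++` cluster proposes
`[max leftmost-mate end − read_len, max end + upper]` for each breakpoint
(its pairs sit wholly left of both junctions); a `--` cluster proposes the
mirror-image interval from minimal mate starts; a call requires
intersecting proposals in both coordinates, reports the intersections
(width ≤ upper + read_len), and needs total support ≥ 3 by default — a
compromise across 6–30× designs. A lone cluster with support ≥ 2·min
yields a one-sided call flagged as such; whether the original tool
required both orientation classes is undocumented, so the fallback is
explicit in the output. Pairs with mapq < 20 or a spanning flag are
excluded before clustering.

## Long-read caller

Segments shorter than 200 bp are ignored (alignment slop), and junctions
must be contiguous in read space within 100 bp. For a `(+,−)` junction the
plus segment's reference end is the proximal breakpoint and the minus
segment's reference end the distal one; for `(−,+)`, the minus segment's
start and the plus segment's start. A consequence of the reflection
geometry worth stating: a two-segment read crossing only one breakpoint
still pins *both* breakpoints, because the inverted-side segment's far edge
maps to the other junction. Partial and full-span candidates are therefore
consolidated uniformly (the pattern is recorded); consensus breakpoints are
medians over member junctions, intervals are median ± 500 bp, and support
counts distinct reads (≥ 2 by default; read-level quality weighting of the
original caller is undocumented and not modelled). Cross-technology
reconciliation intersects intervals when both breakpoints agree and labels
the merged call `evidence="both"`.

## IP-LCR finder

Seed-and-extend against the reverse complement: k-mer matches (k = 12)
between the sequence and its reverse complement fall on anti-diagonals
(`i + j` constant) for inverted repeats; seeds on nearby anti-diagonals
(≤ k apart) are chained when consecutive seeds are ≤ 500 bp apart and ≥ 3
support a chain; chains are extended ungapped with +1 match / −2 mismatch
and x-drop 20, reporting the maximal-scoring extent. Ungapped extension is
sufficient because the repeat model is substitution-only; it also keeps
megabase self-comparison tractable. Greedy extension may add a few
chance-matching bases beyond a planted copy, so a perfect copy reads
~99.9% identity; the identity estimate is guaranteed within ±0.5 points
for copies ≥ 5 kb and endpoints within k bp (tested). Defaults report
hits ≥ 1 kb at ≥ 90% identity; the NAHR flag applies the stricter > 98%
with a configurable separation window. Direct (non-inverted) repeats and
gapped alignment are out of scope.

## Filter cascade

Stage order: quality → rarity → zygosity → sharing → locus → segregation →
control absence. Rarity uses strict `MAF < 0.01` in every configured panel
(the stricter of the two published phrasings), with absence from a panel
counting as novel/rare. Missing genotypes fail the sharing stage (an
unconfirmed affected carrier is not evidence) but pass the control-absence
stage (an ungenotyped control cannot exclude a variant); both behaviors are
configurable. Segregation requires every genotyped haplotype carrier to
carry the variant and every genotyped non-carrier to be homozygous
reference; fewer than two informative samples is "uninformative". "Good
quality" is QUAL ≥ 30 by default — an explicit stand-in, since the original
platform's internal criteria are proprietary. Stage counts are monotone
non-increasing and stage-k survivors are subsets of stage-(k−1) survivors
(tested invariants).

## Statistics

**Fisher allelic test.** The two-sided p sums hypergeometric probabilities
≤ the observed table's (probability-mass method), computed with exact
integer binomials and a single rational division — float tail-summation
cannot guarantee correct tie handling, and the test suite checks agreement
with an independent rational-arithmetic enumeration to 10⁻¹² over every
table with total ≤ 60. The odds ratio is the sample cross-product with a
Haldane–Anscombe +0.5 on all cells when any cell is zero; the 95% CI is
the Woolf log interval on the (possibly corrected) table. The published
analysis does not state its OR/CI conventions; these are declared here.

**Permutation burden test.** Per-variant scores `s_j = w_j g_jᵀ(y − ȳ)`
with `w_j = Beta(MAF_j; 1, 25)`, combined as
`Q_ρ = ρ(Σs)² + (1−ρ)Σs²` over ρ ∈ {0, 0.25, 0.5, 0.75, 1} — the
burden/variance-component family of the optimal unified test. Each `Q_ρ`
is standardized by its permutation moments and the omnibus statistic is
the maximum; inference is by phenotype-label permutation,
`p = (1 + #{perm ≥ obs}) / (n_perm + 1)`, replacing the analytic
small-sample machinery with exact permutation at desk-scale cost. Sparse
rare-variant genotypes make the statistic discrete (several percent of
permutations can tie the observed value exactly), so ties are resolved by
randomized tie-breaking — the exact-uniform convention — rather than
counted conservatively; null calibration at α = 0.05 is verified over
1000 replicates. Variants at sample MAF ≥ 1% are excluded by definition
of the test. Covariates and relatedness are not modelled.

**Mann–Whitney U** is exact by full enumeration of all C(n+m, n) labelings
when min(n, m) ≤ 10 (midranks make it permutation-exact under ties),
otherwise the tie-corrected normal approximation with continuity
correction. **χ²** is the Pearson statistic without continuity correction;
zero expected counts raise with advice to use the Fisher test.
**Consequence classification** parses HGVS protein tokens (one- and
three-letter): nonsense and frameshift → PTC, single-residue substitution →
missense/synonymous, in-frame dup/del/ins → in-frame indel; unparseable
tokens warn and classify as "other". **Expression normalization** divides
each sample's values by the geometric mean of its reference genes (the
multi-reference-gene averaging convention for qPCR), making normalized
values invariant to per-sample scaling.

## Determinism and problem sizes

Every generator takes an explicit seed; pipeline stages derive seeds from
the master seed as `SeedSequence([master, crc32(stage_tag)])`, so runs are
bit-reproducible (tested byte-for-byte on written outputs). The test suite
and acceptance script use 1 Mb genomes with ~400 kb inversions, 20-replicate
recovery sets per caller, a 200 kb genome with 5 kb repeat copies for the
finder, 1000 null replicates at n = 100 + 100 with 2000 permutations for
burden calibration, and 50 replicates at 558 + 755 for power — sizes chosen
so the whole suite runs on a laptop-class single core in a few minutes
while keeping the Monte-Carlo error of each measured rate well inside its
acceptance band.

## Known limitations

Single-chromosome scenarios; inversions only (no deletions, duplications,
translocations, or inversion genotyping); no gapped repeat alignment; no
breakpoint assembly; pedigree haplotypes do not recombine within the locus;
the burden simulator's effect-size convention (|log₁₀ MAF|-proportional) is
one of several used in power work; and the minimal SAM/VCF dialects cover
what the pipeline emits, not the full specifications (no BAM/CRAM, no
phased or multi-allelic genotypes).
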