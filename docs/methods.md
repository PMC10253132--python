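# Methods

This note documents the models, conventions and numerical choices behind
`binmapqtl`, what the synthetic-data generator does and does not emulate,
and the known limitations of each stage.

## Synthetic F2 populations

The generator is the package's verification instrument: every downstream
stage is tested against populations whose crossovers, genotypes and
genetic effects are known exactly.

**Genome geometry.** The default map has 19 linkage groups with the
template lengths and marker counts of a published *B. napus* bin map
(1618.329 cM, 4148 sites); sites are evenly spaced in cM with collinear
physical positions, and physical chromosome sizes are plausible ZS11-scale
values (the A09 template is 63 Mb so that a QTL at ~82 cM projects near
60 Mb). Only the order and rough scale of physical coordinates matter for
any computation.

**Meiosis.** Crossovers per gamete and chromosome are Poisson with mean
length/100 Morgans, positions uniform (Haldane: no interference). This
makes inter-locus recombination fractions exactly the inverse-Haldane of
the cM distance; the Kosambi inverse used downstream agrees with it to
well below sampling noise at the distances that matter (< 1% absolute
difference below ~15 cM). A gamma-renewal mode (`interference_shape`,
e.g. 2.63) is available to mimic positive interference; it approximates
the crossover process on a single gamete directly by a stationary renewal
with unit intensity per Morgan, which reproduces short-range recombination
fractions but is not a full chiasma-thinning model.

**Sequencing-style genotype calls.** Per site and individual, total depth
is Poisson(4.8) — the study's coverage regime — reads carry the true
alleles with a per-read error flip (default 0.005), and the call is the
set of observed alleles (aa/bb when only one allele is seen, ab when both,
missing at zero depth, plus an independent missingness mask, default
0.02). This is the simplest model that produces the dominant artifact of
low-coverage F2 genotyping: heterozygotes miscalled homozygous at rate
`E[2 (1/2)^k]` over the depth distribution — about 17% at 4.8x — which is
exactly what window genotyping must repair. Real error/missing rates are
not reported for the study data; the defaults are nominal and
configurable.

**Phenotypes.** A latent colour value is the sum of QTL genetic values
(additive code −1/0/+1 toward the yellow allele, dominance deviation
d/a on the heterozygote; F2 variance `a²/2 + d²/4`) scaled so each QTL's
marginal variance share equals its h², plus a Gaussian residual. R is an
affine map of the latent value (location 85, scale 30); G, B, l are
positive and a, b negative affine transforms with small independent noise,
giving |pairwise correlations| >= 0.9 as observed for real colour
channels. The binary visual score is `R > 67`, the empirical valley
between the black-ish and yellow-ish seed classes. Default dominance for
the major QTL is d/a = +0.5 toward yellow (the F1 is yellow-brown).
Note a genuine consequence of the variance-share parametrization: at
h² ≈ 0.21 the three genotype-class means are separated by only ~1.2
residual sd, so the marginal R distribution is *not* formally bimodal —
the generator reproduces the variance decomposition of the mapped QTL,
not the visual bimodality of the real population, which evidently reflects
additional genetic structure beyond the two mapped loci.

**Expression.** Samples follow the study design (2 genotypes x 3 stages x
3 replicates). Genes within a module share a latent stage program
(orthogonal between modules, sd 2.0 log2 units) identical for both
genotypes; per-gene replicate noise (sd 0.25) puts within-replicate
correlations at ~0.98, above the 0.96 floor reported for the real data.
Differential expression enters only through the designated "flavonoid"
set, shifted (default −2 log2) in the yellow genotype at the two late
stages — so the DE truth is exactly that set. The generator does not
emulate count noise, library-size effects, or expression–genotype linkage
(eQTL structure); passing tests therefore show correctness of the network
and selection logic, not robustness to those real-data features.

## Marker filtering

Rules apply in a fixed order (parental polymorphism → depth/missing → MAF
→ segregation) so per-rule drop counts are well defined and sum to the
input count. "Minimum sequencing depth of each allele: 2 (parents) / 3
(F2)" is interpreted as minimum total site depth per individual, the
common reading; a strict per-observed-allele mode is available
(`FilterCriteria(per_allele_depth=True)`). MAF uses F2 calls only, after
depth masking, since segregation-distortion screening concerns the mapping
population. The chi-square test uses the asymptotic df-2 tail without
continuity correction.

## Window genotyping and bins

Windows slide one site at a time and keep full 15-site width wherever the
chromosome allows (a shorter pro-rated tail window appears only in the
non-overlapping step-15 mode). The homozygosity threshold is pro-rated to
`ceil(11/15 x informative sites)` when data are missing; windows with more
than 2/3 missing are unknown. Isolated single-window states flanked by a
common state are absorbed (toggleable smoothing). Window calls map back to
their centre sites; bins are the segments between the union of all
individuals' per-site transitions, so expanding bins reproduces every
individual's window track exactly.

Resolution limits, quantified on noiseless dense simulations: the 11/15
rule is asymmetric (11 sites needed to call homozygous, 5 to call het), so
the detected transition is offset up to ~3 sites toward the homozygous
flank — reported breakpoint intervals are therefore padded by
`window − threshold` sites per side, after which they bracket essentially
every resolvable crossover. Crossover pairs within about one window span,
and crossovers within ~10 sites of a chromosome end, are invisible; this
(not estimation error) is why bin maps shorten at low marker density.

## Linkage map

Pairwise recombination fractions maximize the 9-cell F2 intercross
multinomial likelihood; the double-heterozygote cell mixes phase classes
with probabilities `(1−r)²/2` and `r²/2` and is handled by EM on the
expected recombinant-gamete count. The batched implementation accumulates
all pairwise cell counts as nine indicator-matrix products and runs EM
element-wise. LOD is the base-10 likelihood ratio against r = 0.5.

Grouping thresholds (LOD >= 6, r <= 0.35) are package defaults chosen to
recover the 19 chromosomes on default simulations. Ordering minimizes the
sum of adjacent Kosambi distances: a minimum-spanning-tree traversal seeds
the order and 2-opt reversals polish it; for groups of <= 8 markers this
matches exhaustive search in tests. Map positions are cumulative Kosambi
distances of adjacent pairs (two-step convention: pairwise r, then map
function), with r capped at 0.49 for finite distances. Orientation is
canonical by physical anchor.

Summaries report per-group length, count, mean interval
`length/(count−1)` and max interval; the whole-map mean interval is the
*unweighted mean of per-group means* (this convention reproduces the
template's printed 0.400 from its per-group values), with the alternative
`total length/(markers − groups)` also emitted. Collinearity diagnostics
give Spearman rank correlation between map and physical order, locally
discordant adjacent pairs, and recombination-suppressed spans (default:
> 10 Mb of physical span within < 2 cM).

## QTL scan

Conditional QTL-genotype probabilities at a scan position come from the
flanking bin genotypes through the F2 genotype Markov chain,
`P(Q|M_L,M_R) ∝ T_L[m_L,q] T_R[q,m_R]`, with transition matrices built
from the inverse-Kosambi recombination fractions of the flanking
distances; missing flanks marginalize to the 1:2:1 prior. The scan fits
the Haley–Knott regression `y ~ 1 + cofactors + x_add + x_dom` at 0.5 cM
steps, where `x_add = p_bb − p_aa`, `x_dom = p_ab`;
`LOD = (n/2) log10(RSS_reduced/RSS_full)` with the reduced model dropping
only the QTL terms. With zero cofactors this is exactly single-position
interval mapping, and at a fully informative marker it equals the direct
marker regression. The regression approximation (rather than an EM normal
mixture) is deterministic and accurate at these effect sizes.

Cofactors: greedy forward selection by residual-sum-of-squares reduction
(deterministic; implemented by successive orthogonalization), default 5
markers, excluded within a 10 cM window of the test position; positions
sharing an exclusion set are solved as one batched block. Permutation
thresholds shuffle the phenotype, record the genome-wide max LOD, and take
the (1−α) quantile; with cofactors the full procedure, selection included,
re-runs per permutation (required for exchangeability), while the
cofactor-free path solves all permutations in one batched pass. Null
calibration at the study design point: genome-wide detection at the
α = 0.05 threshold occurred in 4% of 200 null replicates (200 permutations
each).

R² conventions: the reported `r2_single` is `1 − RSS(QTL)/RSS(null)` from
the cofactor-free single-QTL model — the magnitude that matches published
per-QTL variance-explained tables — while `r2_partial`
(`1 − RSS_full/RSS_reduced`) is also emitted. Peaks are greedy maxima
above threshold, separated by >= 10 cM and by a 1-LOD valley; support
intervals span the outermost positions within 1 LOD of the peak, and the
physical interval is the bp range of bins overlapping the cM interval.
The binary visual score is scanned as a numeric 0/1 trait.

**Estimator bias, quantified by simulation** (n = 196, defaults, no
tuning): R² at the *true* QTL position carries the OLS fitting inflation
`(1−h²)·2/n` (~0.8 points); taking R² at the *detected peak* adds a
genome-wide maximization bias, in total ~1–2 points for a 20.95% QTL. For
a minor QTL (6.25%) whose power at the α = 0.05 genome-wide threshold is
~35%, conditioning on detection selects lucky replicates: the conditional
mean peak R² is ~11–12%, nearly double the planted share, while the
unconditional estimate at the true position is on target (~6.8% including
the df term). This winner's curse is a property of the estimand, not an
implementation artifact; `scripts/acceptance.py` reports the conditional
value as defined.

## Coexpression and candidate selection

Unsigned soft-threshold adjacency `|cor|^8` on log2(x+1) expression;
topological overlap
`TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij)` (verified against
a brute-force triple loop to 1e−12). Modules come from average-linkage
clustering of 1−TOM with a *static* cut (height 0.95) — a deliberate,
simpler replacement for dynamic tree cutting; clusters under
`minModuleSize` (default 100) stay unassigned. Eigengenes are the first
principal component of the module's standardized expression, sign-fixed to
correlate positively with the module mean; modules with eigengene
correlation >= 1 − mergeCutHeight (default 0.25) merge iteratively,
closest pair first. Module–trait association uses Spearman correlation of
eigengenes with condition indicators. Edges are retained at weight
strictly > 0.2.

Candidate selection is the three-step intersection: genes overlapping any
peak's physical interval (closed intervals, 1-based, any overlap), that
are DEGs at the key stages (default 25 and 35 days after flowering;
"|FoldChange| > 1" is read as |log2FC| > 1, since a raw-scale reading
would be vacuous — a flag restores the raw-scale reading), and that are
flavonoid-pathway members or have a retained edge to a flavonoid DEG
(optionally restricted to key-module genes). Selection is monotone in the
interval. The two-group stand-in DE test (per-stage Welch t on log2
values, Benjamini–Hochberg FDR) is a lightweight screen for synthetic
data; externally computed DE tables can be supplied instead. The
`delta_delta_ct` utility implements 2^(−ΔΔCt) relative quantification
against a reference gene and control sample.

## Problem sizes and reproducibility

Tests and the acceptance script choose sizes that keep the full
verification cycle at a few minutes of one CPU: recovery experiments use
100–200 replicates at full map density with 200-permutation thresholds;
the type-I experiment uses 200 null replicates x 200 permutations; desk
fixtures use thinned maps (a few hundred sites). All stochastic operations
take explicit seeds; fixture files record their seed in `truth.json`.

## Known limitations

- Variant calling, read alignment, RNA-seq quantification and pathway
  annotation are out of scope; inputs enter as VCF/TSV/GFF3.
- The map is built from adjacent pairwise estimates, not a multipoint
  likelihood; at very low marker density it shortens (window resolution),
  as bin maps do in practice.
- The scan fits one QTL at a time (plus cofactors); no multi-QTL or
  epistasis models, and no logistic model for the binary score.
- Static tree cut and the stand-in DE test are functional equivalents,
  not re-implementations, of WGCNA's dynamic cut and count-based DE
  models; module counts and DEG totals from real studies are not
  reproduced quantities.
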