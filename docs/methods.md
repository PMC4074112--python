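# Methods

This note documents the models, numerical choices and design decisions
behind motupipe, and what the synthetic-data tests do and do not show
about real amplicon data.

## MOTU construction

Reads shorter than 100 bp are removed (boundary inclusive). Clustering is
a deterministic greedy centroid algorithm: identical reads are
dereplicated, unique sequences are processed in order of decreasing read
abundance (ties broken by the lexicographically smallest member id), and
each sequence joins the *first* existing centroid whose representative it
matches at or above the threshold (default 0.97), otherwise it founds a
new centroid. Centroids never move. Production OTU clusterers (Uclust
and kin) add word-count prefilters and reject heuristics that make their
output depend on implementation details; we deliberately substitute an
explicit, fully ordered algorithm so that results are exactly
reproducible and testable against a brute-force oracle. The scientific
content — the 97% similarity threshold — is unchanged.

Pairwise identity is computed on a global (Needleman–Wunsch) alignment
with match +1, mismatch −1, gap −2 (linear), terminal gaps penalised;
identity = identical columns / alignment columns. Among co-optimal
alignments the traceback prefers diagonal, then a gap in the second
sequence, then a gap in the first; this tie-break is part of the
definition so that an independent implementation with the same rule
produces bit-identical values. `N` never matches anything, including
another `N` — conservative and deterministic. A cheap length-ratio bound
(min/max length caps attainable identity) lets the clusterer skip
hopeless comparisons without changing results.

## Consensus taxonomy

Hits are screened at identity strictly greater than 90 and e-value
strictly below 1e−50, with at most ten hits per query (best e-values
kept). Genus: at least eight screened hits congruent, or all congruent
when fewer than eight remain. Species: only for genus-assigned MOTUs of
known phylum; some screened hit must reach 100 − v[phylum] percent
identity, where v is the phylum's mean ITS1 intraspecific variability
(Ascomycota 2.88, Basidiomycota 4.98, Chytridiomycota 7.81, Glomeromycota
9.48, Zygomycota 4.13 — weighted means over a per-species survey,
recomputable with `weighted_variability`); the species name then needs at
least six congruent hits (or all, when fewer). Phylum: majority vote over
screened hits. "Congruent" means exact string equality after whitespace
normalisation — synonym resolution is out of scope. With the default
gates two winners are arithmetically impossible (8+8 > 10, 6+6 > 10); a
lexicographic tie-break is nevertheless in place should the gates be
reconfigured.

The species identity gate deserves a note: read literally, "identity
greater than or equal to the ITS1 variability" is vacuous (identities are
~90–100, variabilities 3–10). The only reading under which variability
functions as a similarity cut-off is identity ≥ 100 − variability, and
that is what is implemented.

MOTUs assigned to the same species, or sharing a subject GI among hits
with identity > 90 and e-value < 1e−45, are merged as connected
components (union-find). The merged record takes the id, representative
and assignment of its most abundant member (ties by id); counts are
summed and member sets unioned. Merging conserves reads and never
increases the MOTU count. After merging, three discard rules apply in
order: non-fungal MOTUs; singletons (one read in the combined dataset);
no-hit MOTUs with fewer than ten reads. A MOTU with an unknown phylum is
treated as putatively fungal — unknowns are handled by the no-hit rule,
not the non-fungal one. The pipeline order (cluster → assign → merge →
discard) matters: the singleton census must happen after merging.

EcM (ectomycorrhizal) status is a genus-level property: a MOTU is flagged
EcM iff its assigned genus is in a user-supplied lookup list.

## Richness estimation

Before rarefaction, one sequence per MOTU is discarded per sample, which
drives the sample's singletons to zero. The published procedure discards
a *random* sequence per MOTU, but every choice produces the same count
vector, so the adjustment is implemented as a deterministic decrement —
identical statistics, no seed dependence.

Rarefied richness is the analytic expectation
E[S] = Σ_m [1 − C(N−N_m, d)/C(N, d)], evaluated with log-gamma functions
for stability at realistic depths. Default depths are 1400 (leaf) and
500 (root) sequences — the lowest depths available in the emulated
datasets — and are configurable. `rarefy_counts` draws from the
multivariate hypergeometric distribution (sampling without replacement),
so Monte-Carlo rarefaction agrees with the analytic value by
construction; tests assert agreement within three standard errors.

Group richness assumes unknown-phylum MOTUs contain group i in the same
proportion as phylum-assigned MOTUs:
R_ij = (N_ij / N_assigned) × ER_j. When the groups partition the
assigned MOTUs, Σ_i R_ij = ER_j exactly. The proportions N_ij/N_assigned
are computed on the unrarefied post-filter counts (they are better
estimated at full depth) while ER_j is computed on the adjusted, rarefied
sample; this is an interpretation — the published description does not
say on which side of the rarefaction the proportions were taken.

Shannon diversity uses the natural logarithm (the base is not specified
in the emulated analysis; nats are the common default).

## Composition statistics

`prepare_composition` rarefies every sample to a common depth, binarises,
and drops MOTUs present in fewer than three plots — rare MOTUs distort
correspondence analysis. CoA follows the standard χ²-metric derivation:
P = X / grand total, standardised residuals
S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}, SVD, eigenvalues = squared singular
values. Rows (samples) are reported in principal coordinates, columns in
standard coordinates — one documented convention among several; the
eigenvalues and inertia fractions are convention-free. CoA obeys
distributional equivalence: splitting a column into proportional parts
leaves row scores unchanged (tested).

The sample dissimilarity is Sørensen, d = 1 − 2a/(2a+b+c), the
presence/absence reduction of Bray–Curtis — the default an adonis-style
analysis would use on a binary matrix; the metric is configurable by
passing any square distance matrix to the PERMANOVA directly.

PERMANOVA uses the Gower-centred matrix G = −½ J D² J and sequential
(Type I) sums of squares in the stated term order (region, soil pH,
temperature, site-within-region), each term's SS being tr[(H_k −
H_{k−1})G] for the growing hat matrices; pseudo-F uses the residual mean
square. Degrees of freedom come from rank increments (SVD with a relative
1e−10 tolerance), so collinear terms are detected and reported.
P-values permute samples only within strata (the region blocks), which
keeps the test valid under the nested design:
p = (1 + #{F* ≥ F}) / (1 + n_perm), with a seeded generator. For tiny
designs an exhaustive mode enumerates all within-strata permutations and
returns the exact permutation p. Permutations act on the distance matrix
with the design held fixed, the standard adonis scheme.

Environmental screening: Pearson correlation table with two-sided t
tests (n−2 df); PCA of standardised variables (correlation-matrix PCA)
reporting variance fractions and per-variable axis contributions (squared
orthonormal loadings × 100); and a quadratic richness–temperature fit
y = b0 + b1·T + b2·T², with a two-sided t test on b2 and the peak at
−b1/(2·b2) when the curve is hump-shaped — the mid-domain-effect check.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the hierarchical design of a three-region
mountain survey: 3/5/3 elevation sites per region, three plots per site,
each plot sampled in leaf and root habitats (66 samples), with per-sample
sequencing depths drawn uniformly from the printed per-habitat ranges
(leaf 1506–15830, root 552–3622). Uniform depth sampling matches the
published ranges without inventing a depth distribution. Within a region,
site temperature falls with elevation (lapse ≈ −0.55 °C / 100 m plus
0.2 °C noise), precipitation rises with elevation, and soil pH and
nutrient contents are drawn independently of elevation — mirroring the
observed correlation structure (everything tracks elevation except pH).

Communities: taxa draw a category from the simplex (Ascomycota 0.554,
Basidiomycota 0.310, Zygomycota 0.032, other 0.003, unknown 0.101 — the
non-singleton composition being emulated). "Unknown" taxa keep a real
phylum in the ground truth (distributed like the assigned fraction) but
their taxonomy is withheld from hit tables — that is how unknowns arise
in practice, and it gives the group-richness estimator a well-defined
truth. About 31% of basidiomycete genera (and 2% of ascomycete genera)
are flagged ectomycorrhizal.

Relative abundances default to a Zipf rank-abundance curve with exponent
1.6. A lognormal family is also available, but no lognormal parameter
reaches the observed ~38% combined-dataset singleton fraction at these
depths — the realised fraction saturates near 30% because widening the
distribution removes taxa from the observed set as fast as it adds
singletons. The Zipf exponent was calibrated once by Monte-Carlo (target
0.378 at pool 5000 and default depths; realised 0.39 ± 0.02) and is not a
tuning knob for any other test.

Each taxon has Gaussian niche responses to temperature (SD 2 °C) and pH
(SD 1 unit) with independent optima drawn uniformly over the observed
ranges; per-sample counts are multinomial over niche-modulated
abundances. This is the simplest mechanism that produces the
composition–environment covariance the PERMANOVA stage must detect; a
breadth of 0 collapses the niche to a delta function on one site's value
(used to test confinement). Reads are iid-substitution copies of random
150–300 bp ancestors; BLAST tables carry a configurable number of
genus- and species-congruent hits, identity noise around a per-taxon true
identity (default 98–100%, above every phylum's species gate), log-uniform
e-values below 1e−50, and decoy taxonomies drawn from other pool members
*in a different genus*, so the congruent-hit count is exactly the
configured one.

Not emulated: 454 flowgrams and homopolymer errors, chimeras, MID/adaptor
structure, habitat-specific taxon pools, phylogenetic correlation between
abundance and taxonomy, and synonym ambiguity in reference taxonomies.
Passing tests therefore demonstrate the correctness of the *algorithms*
under a clean, known-truth data model — not robustness to sequencing
artefacts, which the upstream denoising steps of a real study are
responsible for.

## Problem sizes used in the routine checks

The automated checks run the estimator-recovery analysis at pool 2000
(20 seeds, root depth 500), the singleton calibration at pool 5000 (10
seeds), PERMANOVA calibration with 1000 effect-free simulations of a
12-sample nested design at 99 permutations (type-I error within
[0.03, 0.07] with and without strata), and the power analysis at the full
33-sample design (100 seeds, 199 permutations; temperature detected in
every run at the default niche settings). The acceptance script uses the
same machinery with seed-derived replicates.

## Known limitations

- The greedy clusterer is quadratic in the number of unique sequences per
  identity check; it is intended for method-level analyses and synthetic
  benchmarks, not for multi-million-read production runs.
- Sequential (Type I) sums of squares make the PERMANOVA table depend on
  term order, as in adonis; the printed order (region, pH, temperature,
  region:site) is the default.
- The merged MOTU inherits its most abundant member's assignment; if two
  merged members disagree at the genus level the minority information is
  dropped.
- Group-richness truth recovery is unbiased in the mean but individual
  synthetic runs fluctuate by a few percent, because one run's pool gives
  all of its plots correlated composition noise.
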