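# Methods

## Scope and data model

The package analyses a rooted phylogeny with branch lengths (ideally an
ultrametric chronogram, branch lengths in time units) together with a
site × taxon incidence matrix whose sites are biogeographic subregions.
Ultrametricity is never assumed silently: `PhyloTree.is_ultrametric`
checks that all root-to-leaf path sums agree within a relative tolerance
(default 1e-6, configurable), and every metric is well defined on plain
additive trees too. Leaf labels must be unique; branch lengths must be
non-negative and present (a permissive parse mode zero-fills missing
ones); a length on the root edge is dropped, since rooting conventions
are handled by the diversity metrics themselves. Any value > 0 in the
incidence matrix counts as presence.

## Mean-path-length dating ("MPL-lite")

To obtain a chronogram from additive branch lengths the package dates
nodes by mean path lengths: age(leaf) = 0, age(v) = mean over children c
of (age(c) + branch(c)). Calibrations fix the age of the MRCA of a leaf
pair; every uncalibrated node is rescaled by the factor that maps its
nearest calibrated ancestor's raw age onto the assigned age, and ages
are clamped (child := min(child, parent)) so they weakly decrease toward
the tips. Branch lengths are rebuilt as age differences, giving an
ultrametric result (relative tolerance better than 1e-9 in the tests).
The rate-deviation smoothing and reference-node statistics of full
dating programs are deliberately not reproduced: dating here exists only
to standardise branch lengths, not to estimate divergence times, and the
simple estimator keeps the procedure transparent and exactly testable.
Conflicting calibrations (a descendant assigned an older age than an
ancestor) are an error, not silently clamped.

## Alpha diversity and the sample.pool null

Faith's PD is computed in its **rooted** form: the spanning subtree of a
taxon set always includes the path to the root, so PD of a single taxon
is its root-to-tip depth and PD of the full leaf set is the total branch
length. This matches the convention of the community-phylogenetics
software lineage this package follows; `rooted=False` gives the
taxa-only spanning subtree for comparison with tools that use it.

MPD and MNTD are computed from the patristic distance matrix (depths
minus twice the MRCA depth, one post-order sweep). For a single-taxon
site both are undefined and reported missing rather than zero.

NRI/NTI are standardized effect sizes under the *sample.pool*
randomization: null communities are uniform random subsets, without
replacement and of the observed richness, of the pool of taxa occurring
in at least one site (the pool can also be supplied explicitly, e.g.
when the analysis set is a subset of everything collected). Defaults:
999 randomizations. z = (observed − null mean) / null sd with the
sample sd (ddof = 1); the two-tailed p is the rank-based
p = 2·min(r, n+1−r)/(n+1) where r is the mid-rank of the observed value
among observed + null. A site equal to the whole pool has a degenerate
null (sd = 0); the result is flagged and z reported as missing, never a
silent NaN.

**Sign convention.** NRI and NTI are reported as the raw z-scores:
positive = phylogenetic evenness, negative = clustering. Much published
software multiplies by −1; users comparing outputs must negate. The raw
orientation is kept because the downstream interpretation here (evenness
as a refugium signature) reads most naturally in it.

Randomization seeds are derived per site by SHA-256 hashing of the
master seed with the site ID, so adding or removing one site never
perturbs another site's null distribution, and all results are exactly
reproducible from one integer.

## Beta diversity

* **Dpw** averages patristic distance over *all* cross pairs between two
  sites, so taxa shared by both sites contribute zero-distance pairs
  (the `comdist` convention). Consequently Dpw of a site against an
  identical copy equals MPD·(k−1)/k, not MPD.
* **Dnn** averages the two directed mean nearest-neighbour distances;
  an alternative (pooling all nearest-neighbour distances) exists in the
  literature, but averaging was chosen as the symmetric default.
* **UniFrac** is the unweighted (presence/absence) form on rooted
  spanning sets, consistent with rooted PD: unique branch length over
  union branch length, in [0, 1], 0 iff the spanning sets coincide.
  Where a study names a "Bray–Curtis-type" PD dissimilarity without a
  formula, this unweighted UniFrac is the interpretation implemented;
  the Sørensen-on-branch-lengths alternative (PhyloSor) can be derived
  from the same edge classification if needed.
* **Bray–Curtis** in binary mode equals the Sørensen complement
  1 − 2|A∩B|/(|A|+|B|); in count mode Σ|x−y|/Σ(x+y) (used for
  family-composition tables, whose cells are numbers of taxa per
  family). Regional-ecosystem composition reuses the binary mode on a
  site × RE incidence table.

Sites with no taxa have undefined dissimilarities and are dropped from
the matrices with a logged warning (the distance-matrix container
enforces finite, symmetric entries).

## NMDS

Kruskal-style non-metric MDS: alternate isotonic (PAVA) regression of
configuration distances on the dissimilarity order with a Guttman
majorization update, minimising stress-1 =
sqrt(Σ(d − d̂)² / Σd²) over the upper triangle. Ties in the input
dissimilarities get Kruskal's primary treatment: tied blocks are
re-ordered by current configuration distance each iteration, so ties do
not constrain one another. Convergence when the stress improvement
falls below 1e-6 (default), capped at 500 iterations; the best of 20
seeded random starts is returned. Orientation is arbitrary in NMDS, so
a deterministic convention is imposed: coordinates centered, rotated to
principal axes, each axis reflected so the first site's coordinate is
non-negative. All-equal dissimilarity inputs are degenerate (any
configuration has stress 0) and are returned as such.

## Inference

* **Spearman** correlations use average ranks for ties and pairwise
  deletion of missing values (at least 4 complete pairs required); p is
  two-tailed via the t approximation, or by exhaustive permutation of
  one ranking for n ≤ 9. Constant vectors leave rho undefined (flagged,
  not NaN). Bonferroni adjustment is min(1, m·p) with m the number of
  tests in the family actually computed.
* **Mantel/RELATE**: the statistic is the Spearman correlation of
  corresponding upper-triangle entries; the null jointly permutes the
  second matrix's rows and columns; p is one-tailed for positive
  association, (hits + 1)/(n_perm + 1). When n! ≤ n_perm the null is
  enumerated exhaustively (identity included in the reference set),
  giving exact p on small site sets.
* **PD~SR regression**: OLS of log10(PD) on log10(SR). Base 10 is fixed
  because the slope is base-invariant but the intercept is not, and the
  published intercept this package reproduces is a log10 quantity.
* The correlation suite computes all diversity × attribute pairs twice:
  on all sites and with a configured exclusion list (e.g. depauperate
  outlier subregions), since such sites can dominate rank correlations.

## Synthetic data: what it emulates and what it does not

`simulate_bd_tree` draws constant-rate birth–death trees conditioned on
the number of extant tips (rejection on the simulator outcome), standing
in for a barcode-derived chronogram. `assemble_communities` builds
sites of given richness (fixed, or drawn uniformly from a range) under
three scenarios: uniform-random subsets; *clustered* assembly attracted
to a random seed taxon with kernel weight exp(−s·d/h) (s = strength,
h = tree height); *overdispersed* assembly preferring taxa far from the
already-chosen set with weight exp(+s·min-d/h). Strength 0 reduces every
scenario to uniform random; the default strength 10 produces strongly
detectable clustering/evenness on ~100-taxon trees (mean |z| well above
2 in the recovery simulations). The kernels are written so that larger
strength always means stronger structure.

`generate_attributes` builds per-site attribute tables whose
remnant-rainforest percentage has a target Spearman correlation with PD
via a Gaussian copula (Pearson parameter 2·sin(π·ρ_s/6), which yields
the requested rank correlation asymptotically; |ρ| = 1 short-circuits
to an exact monotone map). The remaining fields are filled with
internally consistent arithmetic (remnant ≤ preclearing ≤ total area;
percentages recompute from the hectare fields).

What the generators do **not** emulate: spatial autocorrelation between
sites, nested site structure, richness–area coupling, detection error
in species lists, and rate variation across the tree. Passing the
recovery tests therefore shows the estimators are correct and powerful
under clean assembly processes, not that real subregion data will
separate as cleanly.

Simulation sizes used by the calibration checks — a 100-taxon tree,
1000 uniform-random sites of richness 10–50 for the null calibration,
200 sites per scenario for sign-consistency, 999 randomizations
throughout — are the package's chosen desk-scale study conditions:
large enough that the ±0.1 calibration bands and 95% sign-consistency
bounds are meaningful, small enough to run routinely.

## Pipeline and conservation report

`run_assessment` chains every stage from file inputs, with one master
seed; per-stage streams are hash-derived, so outputs are byte-identical
across repeated runs with the same configuration. Stage failures leave
a `FAILED` marker naming the stage and retain completed outputs.

The conservation report combines the two priority perspectives the
assessment supports: raw diversity (PD rank) and distinctiveness (mean
UniFrac distance to all other sites). The regional coverage statistic
is the remnant-area-weighted mean of per-site protected percentages,
Σ(pct_PA·RemRF)/Σ(RemRF); sites missing either field are excluded.
A site is flagged priority when its PD rank is in the top third and
less than 17% (configurable) of its remnant rainforest is protected —
an explicit operationalization (the 17% echoes the CBD Aichi target),
not a published rule.

## Known limitations

* MPL-lite dating is a standardisation device, not a divergence-time
  estimator; calibration rescaling is piecewise-linear between
  calibrated nodes.
* Abundance-weighted MPD/MNTD and weighted UniFrac are out of scope, as
  are alternative null models (independent swap, trial swap).
* The exhaustive Mantel path enumerates at most n! ≤ n_perm
  permutations, i.e. it engages only for n ≤ 6 sites at default
  n_perm = 999.
* The Gaussian-copula attribute generator hits the target rank
  correlation only asymptotically; at n = 50 the sample Spearman rho
  scatters around the target with sd ≈ 0.05.
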