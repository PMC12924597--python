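# Methods

This note documents the models and procedures the package implements, the
defaults it chooses where the underlying experimental workflow leaves a
decision open, what the synthetic-data generators do and do not emulate,
and the numerical conventions used throughout.

## Abundance preprocessing

The central object is a protein × sample intensity matrix from label-free
quantification (LFQ) with a sample → group map. LFQ matrices contain
missing values that are predominantly *missing not at random* (MNAR):
low-abundance proteins drop below the identification limit more often.
The preprocessing chain is filter → log2 → impute, all on the protein
level.

**Presence filter.** A protein is retained iff its observed fraction is at
least `min_frac` (default 0.7) within *at least one* group. Evaluating
presence per group keeps group-specific proteins — a protein quantified in
every control but no case is biologically interesting, not noise. The 0.7
default is the common proteomics convention; it is recorded in the run
manifest because it is an assumption, not a property of the data.

**kNN imputation.** For a missing cell (protein *p*, sample *s*) the
k = 10 nearest proteins are found by root-mean-square Euclidean distance
computed over the samples both proteins were observed in (scaling by the
number of shared samples keeps distances comparable across pairs with
different overlap). Neighbours must themselves be observed at *s*; the
imputed value is their unweighted mean. Fewer than k eligible neighbours →
use all; none → fall back to the protein's own observed mean with a
logged warning. Imputation runs on the log2 scale, where LFQ noise is
approximately additive. Under MNAR this estimator is biased upward for
censored cells — an inherent property of abundance-based kNN imputation,
visible in the simulations below.

**Two-group tests.** The Wilcoxon rank-sum test reports the rank sum of
the first group. With n₁+n₂ ≤ 12 and no ties, the two-sided p-value is
exact: every (n₁+n₂ choose n₁) relabelling is enumerated and p is the
fraction with |W − μ| at least the observed deviation (μ = n₁(N+1)/2).
Otherwise a normal approximation with tie correction and a 0.5 continuity
correction is used. A consequence of exactness worth remembering: at
4 vs 4 the smallest attainable two-sided p is 2/70 ≈ 0.029, so the
attainable test size at α = 0.05 is 0.029, not 0.05; calibration
simulations should therefore be read at group sizes (e.g. 10 vs 10) where
the attainable levels are dense near α. Student's t uses pooled variance
(Welch by flag). Multiple testing uses Benjamini–Hochberg throughout.

**Differential expression.** Per-protein Wilcoxon on the imputed log2
matrix; fold change is the difference of group means on the log2 scale
(case − control); significance defaults to BH-adjusted p < 0.05 with no
fold-change cutoff. Both cutoffs are configurable and recorded in the
manifest.

## Ordination and consensus clustering

Classical (Torgerson) MDS double-centres B = −½ J D² J and
eigendecomposes; coordinates are eigenvectors scaled by √eigenvalue, and
negative eigenvalues are truncated (warning if fewer positive eigenvalues
than requested dimensions exist). On a genuinely Euclidean distance matrix
this reproduces all pairwise distances exactly, which the tests assert to
1e-8.

Consensus clustering subsamples ⌈pItem·n⌉ samples without replacement
(pItem = 0.8), runs k-means (k-means++, 10 restarts, Lloyd, max 300
iterations) on each of 50 subsamples, and records consensus(i, j) =
co-clustered runs / co-sampled runs for each k from 2 to maxK = 8. Item
resampling only — features are never resampled. The number of clusters is
picked by the delta-area criterion on the CDF of upper-triangle consensus
values: k = 2 scores its raw area under the CDF, k ≥ 3 the relative
increase over k−1, and the argmax wins. This makes an inherently visual
choice reproducible while the per-k matrices are still emitted for
inspection. Pairs never co-sampled are excluded from the CDF and set to 0
in the final matrix (probability ≈ (1−pItem²)^reps ≈ 1e-22 at defaults).
Final labels at the chosen k come from average-linkage clustering of
1 − consensus. Each (k, rep) pair derives its own seed from the master
seed, so results are reproducible and independent of evaluation order.
Hierarchical clustering of samples defaults to complete linkage on
Euclidean distances.

## Correlation-clique networks

The correlation graph connects proteins with |Pearson r| strictly greater
than 0.7 on the imputed log2 matrix. Zero-variance proteins get r = 0 with
a warning. Maximal cliques are enumerated with Bron–Kerbosch with
pivoting and filtered to sizes 8–20; ordering is deterministic (size, then
mean |r|, then members). Because "a specific subset of highly correlated
variables" is not an algorithm, network selection is made explicit:
greedily accept cliques by descending mean |r| whose Jaccard overlap with
every accepted network is ≤ 0.5, up to 3 networks, labelled A, B, C.
Both knobs are configurable and logged.

The intra-network group comparison uses the mean Fisher-z-transformed
within-clique pairwise correlation, group 1 minus group 2; Fisher's z
stabilises the variance of r. The null distribution comes from permuting
sample group labels (default 999 permutations), with the add-one two-sided
estimator p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1), which is never
smaller than 1/(n_perm+1) and super-uniform under the null.

Over-representation is the upper-tail hypergeometric probability of the
observed overlap between the query (e.g. significant proteins) and each
gene set, BH-adjusted across sets. Gene sets are intersected with the
universe first. The universe defaults to the *detected* proteins — the
~250-protein citrullinome — not the whole proteome; the background is the
single biggest lever in enrichment analysis, so it is an explicit argument
rather than a hidden default.

## Structure comparison

PDB I/O is fixed-width v3.3 (coordinates to 3 decimals, B-factors to 2);
nonstandard residues such as citrulline (`CIR`) are ordinary residues to
every operation. Kabsch superposition pairs atoms by (chain, residue
number, atom name) — PTM variants preserve numbering, so no sequence
alignment is performed — and constrains the rotation to det(R) = +1.
Global RMSD is over the fitted atom set (Cα by default); per-residue RMSD
decomposes it exactly (the atom-weighted RMS of per-residue values equals
the global value to machine precision).

Backbone torsions follow the IUPAC sign convention:
φᵢ = dihedral(Cᵢ₋₁, Nᵢ, CAᵢ, Cᵢ), ψᵢ = dihedral(Nᵢ, CAᵢ, Cᵢ, Nᵢ₊₁), in
degrees in (−180, 180]; a C–N distance above 2.5 Å is treated as a chain
break. Secondary structure is assigned from (φ, ψ) windows chosen to
capture ideal α (−57, −47) and β (−120, +130) geometry with generous
margins: H for φ ∈ [−100, −30] and ψ ∈ [−80, −5]; E for φ ∈ [−180, −90]
and ψ ∈ [90, 180] ∪ [−180, −170]; otherwise coil. Provisional helix runs
shorter than 4 and strand runs shorter than 3 are demoted to coil,
mimicking the minimum lengths of real elements. Windows and run lengths
are arguments.

Polar contacts approximate hydrogen bonds by heavy-atom N/O pairs within
3.5 Å, with no angular criterion — predicted models carry no hydrogens, so
a distance cutoff is the honest resolution of the data. Same-residue pairs
and sequence-adjacent same-chain pairs are excluded (the backbone
carbonyl O sits ~2.2 Å from the next residue's N through the peptide
bond, which is covalent geometry, not a contact). The composite
native-vs-modified report chains superposition → RMSD → B-factor deltas →
torsions/SS on both → SS transitions → contacts on both → gained/lost
contacts keyed by (chain, residue, atom) pairs, flagging residues within
±3 of the modification site. B-factors are compared as stored and
labelled neutrally, since predicted models store per-residue confidence
(pLDDT) in that column.

## Peptide tiling

A protein of length L yields L−11 overlapping 12-mers at single-residue
steps. The citrulline variant replaces every R with 'X' and the
homocitrulline variant every K with 'Z' (symbols configurable; they must
fall outside the 20-letter alphabet; the FASTA output records the
mapping in each record description, as the arrays are synthesised, not
translated). Tiles without the target residue are kept, flagged
unmodified, so positions align across variants. Ratio analysis reports
mean(case)/mean(control) per tile × variant × isotype on the raw scale
(array intensities are multiplicative), compares groups with a pooled
t-test on log signals (one-way ANOVA for more than two groups), adjusts
BH within each variant × isotype stratum, and correlates ratio profiles
between isotypes with Pearson r. A zero control mean flags the ratio as
undefined rather than producing an infinity.

## Synthetic data: what it emulates and what it does not

`gen_lfq_dataset` produces log2 intensities
x = baseline + loading·module factor + group effect + noise, with
baseline ~ N(25, 2) per protein, module latent factors ~ N(0, 1) shared
within planted modules (default sizes 30/20/15 of 250, loading 0.8 →
intra-module r ≈ 0.7), six planted effects of |log2FC| = 2 (five up, one
down in the case group), and residual noise sd 0.5. Missingness is MNAR
by construction: cell masked with probability sigmoid(−(x − 21)), i.e. a
logistic detection limit two standard deviations below the typical
protein, giving ~8% overall missingness concentrated in the bottom
intensity decile. Differential effects are planted on non-module proteins
whose baseline is comfortably above the detection limit (≥ midpoint + 2 +
|fc|): a protein *at* the limit loses one whole group to censoring, which
would conflate "effect present" with "protein unquantifiable" and is not
the phenomenon the ground truth is meant to encode — the differential
citrullinated proteins this workflow targets (complement components in
serum) are mid-to-high abundance. The defaults match the profiled cohort:
250 proteins, 10 case vs 10 control samples.

The generator emulates intensity-dependent missingness, correlated
modules and additive group shifts. It does **not** emulate peptide-level
inference, shared-peptide effects, between-run normalisation drift,
heavy-tailed or protein-specific noise, or correlation between the DE
effect and module structure — so passing recovery tests demonstrate the
pipeline's correctness under its stated model, not its power on any real
cohort.

Toy structures are built by natural-extension (NeRF) chain growth with
ideal internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
C=O 1.231 Å, standard angles, ω = 180°); only φ/ψ vary. Side chains are a
single CB; named polar pseudo-atoms can be appended to engineer contact
fixtures. `perturb_structure` displaces residues within a ±3 window of
the site along a seeded random direction with linearly decaying weight
(maximum = `magnitude` at the site) and renames the site residue ARG→CIR,
emulating a local, site-centred deviation; everything else is
bit-identical. `gen_ring_multimer` places rigid copies of a chain at
equal angles around the z axis, chains A, B, …, mimicking the pore-shaped
multimer of a terminal complement assembly. `gen_array_signals` gives
every tile log-normal background (ln-mean 7, ln-sd 0.5) and multiplies
case-sample signals of citrulline-variant tiles overlapping a planted
epitope by the effect (default conditions 12 cases vs 12 controls,
matching the array cohort) — reactivity is citrulline-specific, so native
and homocitrulline tiles are untouched.

## Numerical conventions and problem sizes

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the CLI derives per-stage seeds from one
master seed. Tolerances: MDS distance reconstruction 1e-8; Kabsch rigid
recovery and determinant 1e-9; torsion round trips 1e-6°; RMSD
decomposition identity 1e-12. Ties in kNN neighbour selection break by
protein order (stable sort); clique and contact orderings are fully
deterministic. The acceptance script measures recovery at the study scale
(250 × 20 matrices, 20 simulation seeds; 10 consensus seeds; 2000
Wilcoxon null draws; 60 clique-oracle graphs; 300 permutation-test
replicates at 999 permutations), sizes chosen to keep Monte-Carlo error
well below the decision margins of each check.

## Known limitations

* kNN imputation under strong MNAR biases censored cells upward;
  fold-change estimates of heavily censored proteins shrink toward zero.
* The delta-area rule inherits consensus clustering's known tendency to
  over-partition weakly structured data; the per-k matrices should still
  be inspected.
* The hypergeometric ORA treats proteins as exchangeable and ignores
  protein size / detectability bias.
* The distance-only contact criterion cannot distinguish hydrogen bonds
  from close polar approach, and the SS windows are heuristic — both are
  adequate for comparing two conformers of the same sequence, their
  intended use.
* Structure comparison assumes conserved residue numbering; it does not
  align sequences and will silently skip residues absent from one form.
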