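# Methods

`varloc3d` asks where protein-altering variants of different origins fall on
a protein — in Pfam domains, protein-interaction interfaces, intrinsically
disordered regions (IDRs), along the sequence, and in three-dimensional
clusters on the structure — and whether those placements differ between
variant classes. The motivating setting is the DNA-damage-response (DDR)
gene family, where germline predisposition variants (pathogenic, benign,
VUS) and recurrent somatic variants (primary vs metastatic tumours) are
hypothesised to hit the same functional regions ("two-hit" synergy), but
every component is generic.

## Variant curation

Variants are protein-level records: gene, 1-based residue position, ref/alt
(one-letter codes, `*` for stop gains, or a consequence tag), origin, and a
class. Frameshifts and stop gains are assigned the first affected residue,
matching how clinical notation (e.g. p.L1908Rfs*2) reports a single
position. Germline clinical-significance strings are collapsed
case-insensitively to three classes (pathogenic/likely-pathogenic,
benign/likely-benign, uncertain-significance); everything else — conflicting
interpretations, drug response, risk factors — is rejected and logged, never
silently dropped. Somatic records pass a recurrence filter: only variants
seen in ≥ 2 tumour samples are retained (putative drivers), and synonymous
changes are excluded. Duplicate rows collapse with summed sample counts.
After curation every retained variant belongs to exactly one of five
analysis classes: pathogenic, benign, vus, primary, metastatic.

Cohort carrier percentages (100 × carriers / n) round half-even at the
requested precision, so published table values reproduce digit-for-digit.

## Feature annotation and localization statistics

Feature tracks are 1-based inclusive intervals (the Pfam/UniProt
convention; a BED importer converts 0-based half-open input). A variant is
"in" a feature kind if its position lies in any interval of that kind; a
variant spanning two domain entries counts once in the per-kind total and
once per label.

Class-wise feature fractions are compared pairwise with the "N−1"
chi-squared test: the Pearson statistic of the 2×2 table scaled by
(N−1)/N, N = n₁+n₂, referred to χ²₁ — the recommended two-proportion test
at moderate counts. Pairwise p-values get a Dunn (Bonferroni-type)
correction, p·m capped at 1, over the m comparisons within a feature kind.

Sequence distributions per class are summarised three ways: histograms in
fixed 75-residue bins (last bin truncated at the protein length; residue 75
falls in bin 1, residue 76 in bin 2), a Gaussian kernel density on the
residue grid with Silverman bandwidth and mass reflection at both sequence
ends (no density leaks outside [1, L]; curves renormalise to unit mass,
tolerance 1e−6), and the two-sample Kolmogorov–Smirnov statistic
D = sup |F̂₁ − F̂₂| with exact small-sample p where feasible. D is this
package's definition of the distribution-difference statistic; the source
analyses cite a distribution-fitting R package without a formula, so KS —
the standard statistic on this scale — is adopted and documented rather
than guessed as equivalent. A sample of fewer than two positions yields an
NA density curve; a degenerate (all-equal) sample gets a unit-residue
kernel at the common position.

## Burden per protein length

Burden is count/length (aa⁻¹), computed per protein and class. Group
comparisons use Welch's unequal-variance t-test (groups of unequal size and
spread) or the Wilcoxon rank-sum test; the rank-sum p is exact (full
enumeration over mid-rank assignments, ties included) for pooled n ≤ 14 and
a tie-corrected normal approximation above. Outliers are never trimmed.
Proteins whose burden strictly exceeds the cohort's 75th percentile
(type-7, linear-interpolation quantile — no convention was stated, so the
numpy default is used) are flagged as accumulators. Pathway aggregation
counts a variant once per pathway of its gene; both the unique-variant
total and the summed contribution total are reported because they diverge
for multi-pathway genes. Excluding a dominating gene from pathway plots is
a report-level flag, not a data filter.

## 3D clustering with a bootstrap null

Each residue of a PDB chain is reduced to one representative coordinate:
the Cα atom (default — robust on low-resolution and Cα-only models) or the
side-chain heavy-atom centroid (falling back to Cα for glycine and
unmodelled side chains). Alternate locations resolve to the
highest-occupancy altloc per atom. Variants map through an optional
sequence→structure numbering table; unmapped variants are returned, never
dropped. Each distinct position counts once regardless of recurrence.

Clusters are complete-linkage agglomerative clusters cut at a maximum
diameter CL = 30.0 Å (merging stops when the merged diameter would exceed
CL, so every reported cluster's maximum pairwise distance is ≤ CL);
clusters with fewer than `min_size` = 3 distinct positions are discarded,
and the flat cut makes clusters disjoint. Because complete linkage is
monotone, the flat cut from scipy's `linkage`/`fcluster` is exactly the
merge-while-≤-CL rule; the bootstrap inner loop re-implements the same
algorithm in a numba kernel (verified identical against the scipy path).

Significance is empirical. For a cluster of k members among n mapped
positions, each of `n_boot` (default 10,000) iterations places n
substitutions uniformly at random without replacement on the structure's
residues, re-runs the clustering, and records the diameter of the tightest
null cluster with ≥ k members (∞ if none forms). The p-value is
(b+1)/(n_boot+1), b = iterations at least as tight as observed; the floor
at 10,000 iterations is 1/10,001 ≈ 9.9 × 10⁻⁵, which is why bootstrap
hotspot analyses bottom out at that printed value. (A p below that floor
cannot be produced by 10,000 iterations.)

Two caveats motivate a second, family-wise measure reported alongside.
First, a tight hotspot can be absorbed into a looser flat cluster when a
nearby decoy merges within CL, hiding the core from the per-cluster test.
Second, ranking each observed cluster against the null of its own size
implicitly searches across sizes, which makes the *minimum* per-cluster p
of a run anti-conservative (measured ≈ 3.5% exceedance at the nominal 1%
on null placements). `analyze_structure` therefore also evaluates every
complete-linkage dendrogram node (every tight sub-cluster with ≥ min_size
members and diameter ≤ CL) at its own size, and corrects the minimum node
p by a min-P (Westfall–Young) adjustment: the same bootstrap null yields,
per iteration, the minimum across-size rank, and the observed minimum is
ranked against that distribution. The result, `p_adjusted` (with the
winning node as `core_members`/`core_diameter`), is the value to threshold
when asking whether a structure carries any significant hotspot; under
uniform placement its minimum over a run is calibrated (measured 1.8% at
the nominal 1%), and a planted 4-variant ≤ 12 Å cluster among 6 uniform
decoys on a 300-residue trace is recovered at p_adjusted < 0.01 in 96% of
replicates. The raw per-cluster p remains the published-table-comparable
quantity.

## uEMD differential mutation score

Within each individual, per-gene mutation counts are rank-normalised:
genes ranked ascending, ties at mean rank, divided by the number of genes
— every individual carries the same total rank mass, removing mutation-load
differences. Per gene, ranks across a cohort's individuals are binned into
100 equal-width bins on [0, 1] (last bin right-closed). The unidirectional
earth mover's distance between a tumor histogram t and a background
histogram g is

    uEMD = Σₖ max(0, Cₖ) / n_bins,   Cₖ = Σ_{j ≥ k} (t_j − g_j),

counting only the cost of moving *excess* tumor mass downward from the
high-rank tail. It is zero whenever background mass dominates every upper
tail — in particular for genes never somatically mutated — nonnegative,
at most 1 on unit-mass histograms, and asymmetric by design. Analyses that
quote uEMD scores above 1 use a different normalisation; with unit-mass
histograms the comparable "high-score" flag threshold is configurable.
Per-gene significance comes from permuting cohort labels of individuals
(p = (1 + #{null ≥ observed}) / (n_perm + 1) against the gene's own null),
with Benjamini–Hochberg q-values; gene-set contrasts (e.g. DDR vs non-DDR)
use the Wilcoxon rank-sum test on scores.

## Network statistics

The interaction network is an input edge list (undirected, no self-loops
or duplicate edges) with a DDR flag per node. Reported statistics are the
mean node degree over a gene set (optionally induced-subgraph degree,
since "average degree of the DDR set" is ambiguous between the two) and
closeness centrality in the Wasserman–Faust component-scaled form
(networkx `wf_improved`), which handles disconnected graphs; isolated
nodes get closeness 0 by convention. Network construction itself
(database aggregation, over-connection filtering, dense-module detection)
is out of scope — the network arrives as data.

## Synthetic data generator

The generator emulates the shape of the real inputs at desk scale and is a
pure function of (config, seed). Protein lengths are log-normal
(μ = 6.1, σ = 1.0 on the log scale, mean ≈ 735 aa) clipped to the observed
44–7,968 aa range; the DDR fraction defaults to 229/1411. Domain and IDR
intervals are non-overlapping and cover a configured sequence fraction
exactly up to rounding (defaults 0.25 and 0.20); interface residues
(default 0.12 of the sequence) are drawn with a configured overlap with
IDR residues (default 0.5), reflecting how interaction surfaces favour
disordered segments. Class counts default to the curated-dataset
proportions (pathogenic 10,301 : benign 1,117 : VUS 28,248 : primary
5,795 : metastatic 2,030) scaled down tenfold. Variant positions follow a
per-residue mixture with multiplicative enrichment weights θ_domain and
θ_interface (θ = 1 is uniform; with domain coverage c the expected
in-domain fraction is θc/(θc + 1 − c)).

Structures are Cα traces with exact 3.8 Å virtual bonds: ideal α-helix
geometry (1.5 Å rise, 100°/residue, radius solved so the bond length is
exactly 3.8 Å) or a self-avoiding random walk whose non-bonded pairs stay
≥ 4.0 Å apart (backtracking on dead ends). A full-atom model is
unnecessary because the cluster statistics depend only on one
representative point per residue. Planted 3D clusters choose k residues
inside a ball of diameter d, guaranteeing pairwise distances ≤ d. Cohort
matrices are Poisson: counts ~ Poisson(rate_gene × exposure_individual)
with log-normal gene rates (σ = 0.5) and individual exposures (σ = 0.3);
driver genes multiply their tumor-cohort rate (default 5×). Ground-truth
labels (enrichment class, planted-cluster id) are written to sidecar
tables only, so recovery tests cannot leak through the analysis-facing
files.

What the generator does *not* emulate: realistic folds and contact
topology, mutational signatures and codon-level mutability, annotation
bias between databases, linkage between variant classes within a gene, and
cohort substructure. Passing recovery tests therefore demonstrate that the
statistics detect the effects they target at realistic sizes and are
calibrated under their stated nulls — not that real curated datasets are
bias-free.

## Problem sizes and numerical choices

Simulation-based checks run at desk scale, chosen so the full suite stays
in minutes: bootstrap calibration uses 500 replicates of 10 uniform
variants on one 300-residue trace at 2,000 iterations; planted-cluster
power uses 200 replicates at the default 10,000 iterations; uEMD driver
recovery uses 200 genes × 200+200 individuals × 100 replicates. The
recurrence filter is applied pooled across tumour types (per-type
recurrence was left unstated). Quantiles are type-7; KDE bandwidth is
Silverman's rule with an IQR guard; complete-linkage ties break by scipy's
deterministic merge order; densities renormalise to unit mass on the grid;
cancellation noise below 1e−12 in the uEMD cumulative sums is snapped to
zero so the zero-score semantics are exact.

## Known limitations

Per-cluster raw p-values are valid for a single pre-specified cluster size
but their minimum over a run is optimistic — use `p_adjusted` for
discovery claims. Interface and IDR tracks are consumed as given;
mis-annotation propagates. The mapper assumes one representative
coordinate per residue and a single chain; inter-molecular clusters across
chains are out of scope. Homology models are read as ordinary PDB files —
model quality (and the atom convention on sparse models) directly affects
cluster diameters, so low-resolution structures warrant the Cα convention
and caution within a few Å of CL.
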