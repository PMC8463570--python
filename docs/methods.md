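# Methods

This note documents the models and procedures implemented in
`cophylorestrict`, the assumptions behind them, the parameters that
matter, and the choices made where the design was genuinely open.

## Host-source classification

Each ASV is classified from the binary incidence matrix and the sample
metadata alone. The designation-relevant host groups are the four wild
ape species (a wild bonobo, chimpanzee, gorilla, or orangutan sample
counts toward its species) and humans (either lifestyle,
industrialized or non-industrialized). Captive-ape occurrences are
deliberately ignored: animals in shared zoo environments exchange
strains readily, so captivity carries no information about intrinsic
host association. The ASV's *wild profile* is the set of groups whose
samples contain it; |profile| = 1 → host-restricted to that group,
≥ 2 → mixed-host, 0 → unique-to-captive.

## Maximal-clade extraction

The clade scan answers: what are the largest monophyletic groups of
ASVs that share a host-source category? It runs three sequential
passes over the symbiont phylogeny — host-restricted, then mixed-host,
then unique-to-captive — each a greedy preorder traversal that accepts
a node when

1. its candidate members satisfy the pass's category rule,
2. its bootstrap support strictly exceeds `min_support` (default 50),
3. its members occur in at least `min_individuals` (default 5) distinct
   samples,

and, upon acceptance, does not descend further. An accepted ancestor
therefore suppresses all descendant candidates, which is what makes the
reported clades maximal. Tips accepted in one pass are *consumed*:
later passes see only the leftovers, so candidate members in passes 2–3
are a node's unconsumed tips, and all reported clades are pairwise
disjoint. The pass-2 rule is that the members' pooled wild profile
spans ≥ 2 groups; the pass-3 rule is that it is empty. Captive-only
tips nested inside an accepted mixed-host node are consumed by it;
otherwise they remain available to pass 3.

Design points:

- **Missing support = 0.** Unlabeled internal nodes cannot anchor a
  clade; this is the conservative reading and is applied uniformly.
- **Single ASVs are never clades.** Tips carry no bootstrap support, so
  the support threshold is undefined on them; host-restricted singletons
  appear in the classification table only.
- **`n_individuals` counts samples of any group** containing ≥ 1 member
  ASV, not only samples of the restricted host. Both interpretations are
  computable from the outputs; this one is the default and is recorded
  in the clade table.
- **Monotonicity caveat.** Raising `min_support` or `min_individuals`
  never lets the host-restricted pass *cover more tips*, but it can
  *increase the clade count*: a rejected parent may split into two
  accepted children, and host-restricted leftovers may pool into new
  mixed-host clades. The property suite asserts the coverage form.

Equivalence with a brute-force scan (enumerate every internal node,
apply the predicate, keep nodes with no accepted proper ancestor) is
asserted on 200 random instances in the acceptance suite.

## Fixed-margins clade-size null

Large host-restricted clades could in principle arise from uneven
sampling alone. To calibrate this, the incidence matrix is randomized
under the curveball algorithm: each trade picks two random rows and
reallocates the columns in the symmetric difference of their presence
sets, preserving every row and column sum exactly. The default chain
length is 5 trades per matrix row, a standard mixing heuristic; margins
are conserved by construction regardless of chain length, and the
3×3 uniformity diagnostic (all six permutation matrices hit 1/6 ± 0.02)
checks mixing. For each of `n_permutations` (default 999) permuted
matrices the classification and clade scan are re-run with the tree
fixed; the summary per permutation is the largest host-restricted clade
size and the clade count. Each observed size *s* receives the add-one
empirical p, (1 + #{permutation max ≥ s}) / (1 + N), which can never be
0 and has floor 1/(N+1) — 0.001 at N = 999.

## Co-phylogenetic congruence tests

All three tests consume a host patristic-distance matrix (from a dated,
ultrametric host tree in Myr), a symbiont patristic-distance matrix,
and a binary association matrix A (symbionts × hosts, entry 1 when the
symbiont is observed in that host; every symbiont needs ≥ 1 host).
`association_from_incidence` builds A from the wild profiles, dropping
captive-only ASVs.

- **Hommola correlation test.** Over all unordered pairs of association
  links, Pearson r between the symbiont distances and the host
  distances. Null: relabel hosts and symbionts independently (permute
  the rows/columns of each distance matrix). If either distance vector
  has zero variance the statistic is undefined; the result carries a
  degenerate flag and p = 1. The statistic is cross-checked against
  scikit-bio's implementation in the test suite.
- **ParaFit.** B and C are principal coordinates of the host and
  symbiont matrices; the global statistic is the sum of squared entries
  of the fourth-corner matrix D = CᵀAB. Null: permute each row of A
  independently (each symbiont's host set is re-drawn). The statistic
  reproduces `ape::parafit` exactly on a frozen instance. Note the
  statistic scales *quadratically* when all distances are scaled by c
  (coordinates are linear in distances, D is bilinear); the p-value is
  scale-invariant.
- **PACo.** Hosts and symbionts are embedded by PCoA; rows are expanded
  to one per association link; the symbiont configuration is
  Procrustes-superimposed onto the host configuration and
  m²XY = residual sum of squares. Both configurations are centred and
  scaled to unit sum of squares before rotation, so m² ∈ [0, 1] and is
  invariant to translation, rotation, and global scaling of either
  configuration (the vegan `symmetric = FALSE` convention would make m²
  depend on the host configuration's scale). The superimposition
  direction — symbiont onto host, matching the dependence of symbionts
  on hosts — survives in the link expansion and the null: which host
  each link touches is re-drawn (the link→host vector is permuted),
  with the symbiont side fixed. Small m² = congruence, so the p-value
  uses the lower tail.

**PCoA and the Cailliez correction.** Principal coordinates are computed
by Gower double-centring of −½D² and an eigendecomposition, keeping
axes with eigenvalue > 1e−8 × the largest. Patristic matrices need not
be Euclidean; when the smallest Gower eigenvalue is below −1e−8 × the
largest, the Cailliez additive constant (largest real eigenvalue of the
standard 2n × 2n companion problem) is added to off-diagonal distances
first, after which no negative eigenvalues remain.

**Host-randomization battery.** The battery runs all three tests with
the true host tree and with a randomized one. Default randomization is
a uniform non-identity permutation of the tip labels, which preserves
the patristic-distance spectrum and isolates label–topology concordance
as the thing being destroyed; a Yule (pure-birth) topology over the
same labels, rescaled to the original root age, is available as a
sensitivity mode. Tests that remain significant under a randomized host
are responding to the existence of host-restricted clades, not to
congruence between the two phylogenies — the central caveat this
package exists to demonstrate.

## Sharing analysis

Pairwise Sørenson similarity 2|A∩B|/(|A|+|B|) over per-sample ASV sets,
for all unordered pairs of captive samples (scope widens to all samples
on request). Pairs are stratified by a four-way relationship rule:
same enclosure; same site, different enclosure; same species at
different sites; different species at different sites (sites compare
equal only when both are non-null; likewise enclosures).

Because sharing values of pairs that share a sample are not
independent, group comparisons permute *sample-level* identities: each
permutation shuffles the metadata tuples (species, site, enclosure)
across samples and recomputes every pair's relationship before taking
the pooled two-sample t statistic. For the enclosure comparison
(same-enclosure vs same-site-different-enclosure) the shuffle is
restricted to within sites, since the contrast is defined inside sites;
all other comparisons shuffle across the whole captive scope. Since all
unordered pairs are present, a metadata bijection leaves the group
sizes invariant. P-values are two-sided add-one, Bonferroni-corrected
across the five-comparison family. A plain label-permutation t-test
(`permutation_t_test`) is provided for flat two-group data; with zero
pooled variance the t statistic is 0 for identical groups and ±∞ for
perfectly separated ones.

## Synthetic-data generator

The generator emulates the structure of a wild/captive ape ASV survey;
it produces no sequences and estimates no trees — bootstrap supports
are simulated, because the pipeline consumes supports rather than
inferring them.

**Host tree.** Fixed hominid topology
(orangutan,(gorilla,(human,(chimpanzee,bonobo)))) with divergence times
1.8 / 6.4 / 8.6 / 15.2 Myr (chimp–bonobo, human, gorilla, orangutan
splits), configurable and validated for nesting.

**Scenarios.**

- `codiversification`: each of `n_clades_per_host` backbone copies
  mirrors the host topology (backbone branch lengths = 0.1 × host Myr);
  each host tip subtends a within-host radiation of `asvs_per_clade`
  tips. Pruned to one representative per host, a single copy is
  topologically identical to the host tree (RF distance 0, asserted).
- `host_switch`: `n_clades_per_host` × 5 radiations joined in a random
  backbone, host labels assigned in a shuffled balanced order —
  host-restricted by construction but topologically discordant.
- `filtering`: one random tree; hosts assigned i.i.d. uniform per tip;
  no planted clade structure. For the three congruence tests this
  regime *is* their permutation null, so p-values are uniform and the
  scenario doubles as a level check.
- `captive_mixing`: codiversification plus captive groups.

Radiation-internal nodes draw supports from Uniform[80, 100]; backbone
and filtering nodes from Uniform[0, 100] (noise). Radiation depths
(~0.05–0.15) are small against backbone depths (~1), making planted
clades tight.

**Incidence.** Each ASV is present in each individual of its generating
host group with probability π (`within_host_prevalence`, default 0.6)
and in individuals of other wild-ape groups with probability ε
(`cross_colonization_rate`, default 0 — host-restriction exact by
construction). In `captive_mixing`, captive individuals carry
human-generated ASVs with probability ρ (`captive_human_acquisition`,
default 0.8, emulating strong displacement of native strains) and
conspecific wild ASVs with probability π(1 − ρ). Groups have
`n_individuals_per_group` = 20 individuals; captives split across two
zoo sites with one enclosure per species per site; humans split evenly
between lifestyles. ASVs that end up in no sample are dropped with a
warning (keeping draws i.i.d.-interpretable rather than redrawing), and
`simulate_scenario` prunes them from the tree so tree tips and
incidence rows always coincide.

**Study-condition sizes.** Scaled-down problem sizes are used
throughout: clade recovery and its curveball calibration run on 5 host
groups × 20 individuals with 3 radiations of 4 ASVs per host (60 ASVs ×
100 samples; 199 permutations); the canonical co-diversified instance
is a single mirrored lineage (the congruence tests are run per lineage,
matching how such tests are applied in practice); the host-switch
false-positive demonstration uses 10 radiations of 8 ASVs per host
(400 ASVs), the radiation size chosen as a conservative scaled-down
version of real surveys, where host-restricted clades average ~19 ASVs;
the filtering level check uses 40 replicates at 999 permutations so the
rejection-rate estimate is meaningfully tighter than the 90% bound it
is compared against.

**What passing does and does not show.** The generator plants presence
probabilities that are i.i.d. across individuals within a group, equal
π for all ASVs, and noise-free metadata; real surveys have overdispersed
prevalence, lineage-specific abundance–prevalence relationships, batch
effects across studies, and sequencing artifacts, none of which are
modelled. Enclosure-level social transmission is not planted either:
captive sharing structure arises only from the species-level
human-acquisition mechanism, so Fig.-4-style enclosure gradients in
real data are *not* reproduced quantitatively by the generator.
Passing tests therefore demonstrate correctness of the inference
machinery under its stated model, not robustness to real-data
messiness.

## Numerical choices

- Empirical p-values are add-one everywhere; p = 0 is unattainable.
- Supports on a 0–1 scale are rescaled ×100 at parse time when every
  labelled value is ≤ 1 (both dialects occur in the wild); thresholds
  are always quoted on the 0–100 scale.
- Host trees are validated ultrametric to a relative tolerance of 1e−6.
- Incidence entries > 0 are binarized at load; all-zero ASV rows are
  rejected with the offending ids named.
- The prominence filter is a strict inequality (> 25 %), as is the
  support threshold (> 50); the individuals threshold is ≥ 5.
- Clade ids are assigned deterministically (per-pass, ordered by member
  tuple), so outputs are independent of newick child order.

## Known limitations

- The curveball chain length (5 × rows) is a heuristic; no formal
  mixing diagnostic beyond the small-matrix uniformity check is run.
- The Hommola null relabels whole distance matrices; for very few hosts
  the discrete permutation space is small and p-values are coarse.
- ParaFit and PACo on a 5-host system have limited resolution; on tiny
  symmetric instances the exact nulls contain isometries that bound p
  away from the floor (the test suite works these bounds out explicitly).
- The permutation unit for sharing tests is configurable only between
  the two schemes described; exchangeability across sites is assumed
  when testing species effects.
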