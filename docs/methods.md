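# Methods

This note documents the models and algorithms `cognet` implements, the
numerical and design choices that were genuinely open, and what the test
suite's synthetic data does and does not establish about real data.

## Data model

A *wordlist* is a flat table of coded forms: taxon (doculect), concept,
optional narrow concept (the grapheme actually represented, used only for
variant detection), optional publication year (absent = contemporary
source; plausibility window 1500–2100 CE), an opaque form transcription,
and a CogID ≥ 1. Cross-alphabet concept alignment (whether a Cyrillic
letter is compared with a Latin letter by shape or by sound) is treated as
given in the concept column; the package never re-derives it, since those
judgements are part of the data, not of the analysis.

Binarization makes one character per attested (concept, CogID) pair, with
column order fixed as: concepts in first-appearance order, CogIDs ascending
within a concept. Determinism here is deliberate — every downstream file is
diffable across runs. Two policies handle concepts a taxon does not attest:

* `zero` (default): absence scores 0 everywhere. This reproduces the
  standard coding of published matrices and makes every character pair
  comparable.
* `missing`: absence scores `?` for the whole concept block, and distances
  use pairwise deletion. This is the defensible choice when alphabets have
  disjoint letter inventories (e.g. Cyrillic-only letters), where absence
  arguably carries no phylogenetic signal. It can leave taxon pairs with no
  comparable characters; such pairs raise an explicit error rather than
  being silently imputed, and bootstrap replicates that hit the condition
  are skipped and counted.

Multiple coded variants for one (taxon, narrow-concept) slot are rejected
by default (they usually indicate a coding error) and accepted with
`allow_variants=True`, in which case each variant's character scores 1 and
parsimony mapping treats the taxon as ambiguous between the variant
classes.

## Distances

Hamming distances, normalized by the number of pairwise-comparable
characters (the convention of distance software on standard-coded data);
raw counts are available for diagnostics. With policy `zero` there are no
missing cells, so pairwise deletion is inert — which is also why the choice
between deletion variants does not affect reproduction of standard-coded
results.

## Tree methods

**Neighbor joining** uses the Q-criterion Q(i,j) = (m−2)d(i,j) − R_i − R_j.
Ties break toward the lowest (row, column) index pair — reproducibility
across platforms mattered more than any statistical argument, and ties are
measure-zero on real data. Negative estimated branch lengths are clamped to
zero after the topology step, because edges feed split systems downstream
and splits cannot carry negative weight.

**BioNJ** shares selection and tie-breaking with NJ but reduces the
distance and variance matrices with the mixing weight λ that minimizes the
variance of the reduced distances, clamped to [0,1] (λ = 1/2 when the pair
variance vanishes). On additive input every λ yields the same topology, so
BioNJ and NJ agree exactly there — one of the test suite's oracles.

**Small parsimony** is Hartigan's count-based algorithm rather than
classical Fitch: it returns the exact unit-cost minimum on arbitrarily
multifurcating trees (classical Fitch can under- or over-count on
polytomies, which matter here because consensus and star-like trees arise
naturally) and accepts ambiguous leaf-state sets. The hot path used by the
parsimony search — binary characters on strictly binary trees — is a
vectorized classical Fitch over bit masks, where the two coincide.

**The quick parsimony search** is intentionally minimal: seeded random
addition order, stepwise insertion minimizing total length (ties to the
first edge in deterministic enumeration order), then a single
nearest-neighbor-interchange sweep accepting strictly improving swaps, one
tree returned. This is the lightest search consistent with
one-tree-per-replicate bootstrapping; it is *not* a serious MP search (no
TBR, no tree islands) and is validated only to stay near the exhaustive
optimum on small matrices.

## NeighborNet

The agglomeration keeps clusters that are chains of taxa with one or two
*active* ends. Cluster pairs are chosen by the NJ criterion on
cluster-averaged distances; the pair of ends to link inside the chosen
clusters is chosen by the same criterion on a refined configuration in
which the two clusters' active nodes count as singletons. Whenever a node
acquires two links, the linked triple (x, y, z) is contracted to two
composite nodes:

    d(u, ·) = (1−w)·d(x, ·) + w·d(y, ·)
    d(v, ·) = (1−w)·d(z, ·) + w·d(y, ·)
    d(u, v) = w·d(x,y) + w·d(y,z) + (1−2w)·d(x,z)

with w = 1/3 (the reference default; configurable). The final chain is the
circular ordering.

Tie-breaking is the one place the published algorithm is genuinely
underdetermined, and implementations differ. Two rules are fixed here:
cluster-pair ties break toward the lowest cluster-index pair, and end-pair
ties prefer linking the tail of the first chain to the head of the second.
The second rule makes a fully tied (equidistant) matrix agglomerate in
input order, which is the least surprising deterministic outcome. Note
that with exactly four clusters the selection criterion *always* ties
between complementary cluster pairs (the row sums make Q equal), so
different implementations can legitimately emit different — equally valid —
cycles on the same input; comparisons against other software should
therefore test arc-compatibility of the resulting splits, not cycle
identity.

Split weights solve the nonnegative least-squares problem over all
n(n−1)/2 circular candidate splits (trivial splits included — leaf edges
exist in any displayed graph) with scipy's Lawson–Hanson active-set solver.
For n = 76 the design is 2850×2850, still desk-scale. Splits below 1e−6
are dropped; the threshold is far below any interpretable edge weight and
exists only to suppress solver noise. Ordinary (unweighted) least squares
is assumed throughout. On circular-decomposable input — in particular any
tree metric — the solution is exact (residuals at machine precision, a
frozen closed-form oracle in the tests) and reduces to the generating
tree's splits and branch lengths.

## Bootstrap and consensus networks

Characters are resampled with replacement to the original count; each
replicate yields exactly one tree. Support is the frequency of the *exact*
bipartition — standard bootstrap proportion semantics; compatible supersets
do not count. Replicate seeds derive from the master seed via a stable
CRC32 hash (`derive_seed`), so any single replicate can be reproduced in
isolation and a support-table cell equals `100 × split_support` of an
independently re-drawn sample with the same derived seed.

A deterministic tie-break has a visible statistical consequence: with two
exactly balanced, incompatible character classes, tied resamples always
resolve the same way, so the expected support of the favored split is
P(majority) + P(tie) ≈ 0.59–0.69 depending on the character count, not
1/2. The tests assert the exactly enumerated expectation rather than the
naive symmetry value.

Consensus networks keep splits with bootstrap frequency ≥ cutoff (default
0.15, matching exploratory practice of displaying competing alternatives);
weight defaults to the frequency (the display is about support structure,
not path lengths; mean inducing branch length is available). Above a 0.5
cutoff the retained splits are provably pairwise compatible; no circular
ordering is claimed at any cutoff, since the system may be genuinely
multidimensional. Externally produced tree samples (e.g. a likelihood
bootstrap from a dedicated ML tool) can be ingested from a one-tree-per-line
Newick file and fed to the same consensus machinery; the package itself
never shells out to external tools.

## Analysis layer

Time filters are inclusive windows over the taxon's source year, plus a
flag for undated (contemporary) taxa. The three shipped presets — up to
1840; 1808–1999 dated only; 1950 onward plus contemporary — encode the
conventional early/middle/modern layering of historical alphabet sources;
the middle window's upper bound is necessarily a judgement call ("late
twentieth century") fixed at 1999 and configurable. After filtering,
now-constant characters are retained: dropping them would silently change
normalized distances relative to a standard matrix treatment.

`concept_support` compares each character's 1-taxa (missing cells excluded)
against the split side the caller designated as the group of interest
(`side="either"` checks both): `exact` requires set equality, `compatible`
requires non-empty containment. Characters with no 1-taxon support
nothing.

`min_changes_per_concept` maps a concept's CogIDs as one multistate
character on a provided tree (leaves not attesting the concept are pruned
first) and reports the exact Hartigan minimum. This is the tree-realized
reading of a median-network change count: it is a lower bound over the
displayed tree, not a full multidimensional median-network construction,
which remains a by-hand analysis.

## Simulator

The generator is the package's testbed, built so that every deviation from
tree-likeness in its output has a known cause:

* **Descent.** Each lineage's taxa sit on a random coalescent-shaped binary
  topology (uniform sequential pair joining). Founders get globally fresh
  CogIDs per concept, so lineages are maximally distinct at time zero.
* **Innovation** is infinite-alleles: along each branch, each concept
  mutates to a *globally fresh* CogID with probability `mutation_prob`
  (default 0.05 per branch — low, in line with the observed stability of
  alphabet forms over centuries). No back-mutation, no convergence: any
  character whose 1-set spans lineages is attributable to transfer, and
  the tests assert exactly that (zero spanning characters at zero
  borrowing).
* **Borrowing** copies single concepts from other-lineage donors;
  **replacement** copies a donor taxon's whole inventory (optionally from a
  designated donor lineage) — the two horizontal modes distinguished in
  comparative work on manual alphabets (isolated loans versus wholesale
  adoption of an international alphabet).
* **Sampling.** A configurable fraction of taxa (default 0.5, emulating a
  roughly even historical/contemporary mix) carries a year uniform in
  1593–1999.

Defaults (4 lineages × 5 taxa, 26 concepts) give a desk-scale analogue of a
one-letter-per-concept alphabet dataset. What passing recovery tests shows:
the pipeline correctly separates lineages when vertical signal dominates,
and support degrades monotonically as borrowing rises. What it cannot
show: robustness to convergent innovation (iconicity-driven similarity),
rate heterogeneity across concepts, or alphabet-inventory mismatch — none
of which the generator emulates, all of which exist in real data. Results
on real alphabets therefore warrant the usual caution even where the
synthetic benchmarks are perfect.

At 10% borrowing the true-lineage split often still reaches full bootstrap
support under the default conditions; the degradation becomes reliable by
30%. The monotonicity test asserts exactly that (non-increasing, strictly
lower at 30% than at 0%) rather than a strict decrease at every step,
which would be asserting Monte-Carlo noise.

## Numerical and formatting details

* NNLS: scipy's active-set solver, converged to solver precision;
  residuals on tree metrics are at 1e−14 in practice (asserted < 1e−8).
* Newick: branch lengths serialized with 10 significant digits; labels
  quoted when they contain structural characters; trees written rooted at
  the internal node adjacent to the lowest-numbered leaf for byte-stable
  output. Parsing goes through dendropy; degree-2 roots are suppressed.
* Splits-NEXUS: Taxa + Splits blocks, `weights=yes`, `confidences=yes` iff
  any split carries support, `CYCLE` with 1-based indices when an ordering
  exists, matrix rows listing the side containing taxon 1. Write→read→write
  is byte-identical.
* PHYLIP distance export replaces spaces in names with underscores (format
  limitation).
* All stage seeds derive from one master seed via CRC32 folding into
  [0, 2³¹); identical config + seed reproduces every artifact byte for
  byte.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to exercise every code path
while completing in seconds: exact-recovery sweeps use 200 random trees of
4–10 taxa; exhaustive parsimony oracles go up to 6 leaves (105 topologies,
all internal labelings); bootstrap behaviour uses 100–2,000 replicates on
4–6 taxa; simulator recovery uses 100 seeds at the default 4×5×26
configuration. The full-data bootstrap analysis (76 taxa, 10,000
replicates) is implemented and exercised by the dataset-dependent
acceptance test when the deposited wordlist is supplied.

## Known limitations

* No likelihood models: ML bootstrapping belongs to dedicated tools; only
  their Newick samples are ingested.
* No planar graph layout or drawing — Splits-NEXUS export targets standard
  viewers.
* The quick-MP search is a bootstrap workhorse, not a topology-search tool.
* Median networks are approximated by tree-realized change counts.
* The NeighborNet cycle is tie-break-dependent where the criterion ties
  (see above); split sets and weights, not cycles, are the stable output.
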