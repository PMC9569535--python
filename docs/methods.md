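# Methods

## Problem and model

`unired-rank` prioritizes candidate protein biomarkers. The user supplies
two lists of UniProt/SwissProt accessions: a **reference list** of proteins
with documented involvement in a disease or pathway, and a **query list**
of candidates to be ranked by their relatedness to the references. The
evidence substrate is a per-species set of *literature clusters* — groups
of proteins whose publication record co-clusters under the Markov cluster
algorithm (MCL) — augmented with three transferable evidence layers:
same-species paralogues, curated complex memberships, and human↔mouse
orthologues.

Each (query `q`, reference `r`) pair is pushed through a strict four-tier
hierarchy and receives the score of the first tier whose predicate holds:

| tier | predicate | score |
|------|-----------|-------|
| InCluster | `q` and `r` share a cluster | 1.0 |
| Paralogue | a paralogue of `q` shares a cluster with `r` | 0.5 |
| Complex | a complex partner of `q` shares a cluster with `r` | 0.5 |
| Orthologue | the orthologues of `q` and `r` share a cluster in the other species | 0.5 |

Once a tier fires, later tiers are not evaluated. Expansion through
paralogues and complexes applies to the **query side only**, so the score
is intentionally asymmetric in `q` and `r`. The *overall* score of a query
is the sum of its pairwise scores over the reference list; queries are
ranked by overall score, descending, ties broken lexicographically by
accession. Proteins outside every cluster were never analyzed by the
literature pipeline and are excluded from scoring entirely (they are
reported in a separate table); a clustered query with no evidence stays in
the ranking with overall score 0 — being analyzed and scoring zero is
distinct from not being analyzable.

### The complex tier: two readings

The tier can be read two ways: (a) a complex **partner** of the query is
co-clustered with the reference, or (b) the reference is itself a
**member** of a complex containing the query. The package defaults to
reading (a) (`complex_mode="partner"`), which keeps the tier parallel to
the paralogue tier — evidence is transferred from a surrogate protein to a
cluster co-occurrence check — and exposes reading (b) as
`complex_mode="member"`. The two are not merged: a pair can satisfy one
and not the other, and tests cover the divergence.

Note one consequence of reading (a): if the reference itself is a member
of the query's complex, it is a complex *partner* of the query and is
trivially co-clustered with itself, so the tier fires under both readings.

## Knowledge base

The knowledge base holds, per species, a cluster set (membership may
overlap; sharing any cluster counts as co-occurrence), a complex table
(complexes with fewer than two members are dropped at load time), and one
record per clustered protein carrying its gene names, paralogues,
orthologues, complex ids and reviewed-mapping flags. Records exist **only**
for clustered proteins; evidence referencing unclustered proteins is kept
on the record but is inert — an unclustered paralogue can never satisfy a
cluster co-occurrence check — and such accessions are collected in an
`unresolved` set for provenance. Reviewed-mapping flags are stored and
round-tripped but play no role in scoring.

Source tables are fixed, headered, tab-delimited dialects (documented in
the README); real Ensembl/ComplexPortal exports must be pre-converted.
Accessions are normalized by trimming, uppercasing and stripping isoform
suffixes (`P04637-2` → `P04637`), applied to a fixed point so
normalization is idempotent. The assembled base serializes to JSON with
sorted keys: serialization is deterministic (byte-identical on re-run) and
lossless, and loading validates structure explicitly, naming the missing
or offending key.

## MCL clustering

Clusters can be regenerated from a weighted protein-association edge list.
The implementation follows the standard flow simulation: add self-loops
(weight = the node's maximum incident edge weight; 1.0 for isolated
nodes), column-normalize to a stochastic matrix, then iterate expansion
(matrix power, default 2), inflation (entrywise power, default 2.0, then
column renormalization) and pruning, until the maximum absolute entry
change falls below tolerance. Clusters are read from the attractor rows of
the limit matrix: rows with diagonal mass ≥ 1e-8 are attractors, a node
joins the cluster of every attractor row in which its column has mass
≥ 1e-8, attractors appearing in each other's supports merge into one
attractor system, and multi-membership of ordinary nodes is retained.

Numerical choices, all overridable via `MCLParams`: prune threshold 1e-5
(each column's maximum entry is always kept, so pruning can never empty a
column), convergence tolerance 1e-6, at most 200 iterations (on
non-convergence the current matrix is interpreted and a `RuntimeWarning`
is raised). The production path uses `scipy.sparse` CSC matrices; the test
suite checks it against an independently written dense iteration (no
pruning, tolerance 1e-12) on graphs of up to 12 nodes, and checks
permutation equivariance and exact recovery of planted blocks.

## Permutation significance

The observed statistic is the sum of the overall scores of the analyzable
query proteins. The null is built from random query lists of the same size
drawn uniformly without replacement from the **sampling universe**: all
clustered proteins of the analysis species minus the reference list
(excluding references avoids trivially inflating null scores; proteins
never scored are not counted as zeros — they are simply not in the
universe). Defaults: 1000 permutations, a fixed seed that is echoed in the
output. The p-value uses the plus-one estimator

    p = (#{null sums >= observed sum} + 1) / (n + 1),

one-sided (high scores significant), bounded in [1/(n+1), 1], never zero,
and valid under exchangeability. Because pair scores are independent
across queries, each universe protein's total against the fixed reference
list is precomputed once and every permutation reduces to summing `k`
lookups, so 1000 permutations cost essentially one pass over
universe × references.

Scores are multiples of 0.5, so null sums are discrete and the estimator
is slightly conservative under the null (ties between the observed and
null sums count against significance). The calibration test is designed so
this bias stays well inside its acceptance band: the fixture's evidence
density gives null sums spread over dozens of distinct values, and each of
the 500 repetitions uses 199 permutations so that the 0.05 threshold is
exactly attainable (p = 10/200).

## Synthetic fixtures

The generator emulates a cluster release plus annotation dumps: a
background of `n_proteins` per species assigned uniformly to `n_clusters`
clusters, with paralogue pairs, complexes (2–5 members) and one-to-one
orthologue links sampled at configurable rates among background proteins
only. The planted module adds, per tier, query proteins wired to dedicated
reference clusters such that **exactly one** tier can fire for exactly one
reference: planted queries sit in their own clusters, carry no background
annotation, and earlier-tier predicates are falsified by construction
(e.g. a paralogue-tier query is co-clustered with nothing but itself, and
only its paralogue sits in the reference's cluster). A manifest records
the expected tier, reference and evidence pair for every planted query;
the end-to-end tests replay the pipeline against it. Generation is a pure
function of the spec and seed; the same seed yields a byte-identical KB
JSON.

Defaults (300 proteins/species, 30 clusters, paralogue rate 0.1, complex
rate 0.05, orthologue coverage 0.3, 10 references, 2 planted queries per
tier plus 2 evidence-free) give a small but structurally complete base
that exercises every code path in well under a second. What the generator
does **not** emulate: literature co-citation statistics, power-law cluster
sizes, many-to-many orthology, or the error modes of real identifier
mappings — passing tests demonstrate correctness of the scoring logic, not
performance of the evidence layers on real data.

Test problem sizes were chosen to keep the full suite fast while leaving
the statistical checks meaningful: the enrichment fixture uses 200
background proteins and 1000 permutations; the calibration check uses 240
background proteins, 20 references, query size 10, 199 permutations and
500 repetitions.

## Known limitations

- Only human and mouse are supported; the orthologue tier assumes exactly
  these two species.
- The scoring scheme is fixed weights, not confidence-calibrated; the
  `ScoreScheme` fields are exposed but there is no fitting machinery.
- Cluster construction from literature (the upstream text-mining pipeline)
  is out of scope; MCL here operates on a user-supplied weighted graph.
- With `complex_mode="member"` the evidence pair reported is the
  query/reference pair itself, since no third protein mediates the match.
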