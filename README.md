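# unired-rank

Ranking of candidate protein biomarkers against a disease reference list,
using literature-derived protein clusters with paralogue, complex and
orthologue evidence transfer.

## Who this is for

Wet-lab and computational biologists who have (i) a **reference list** of
proteins with documented involvement in a disease or pathway and (ii) a
**query list** of candidates (e.g. hits from a high-throughput screen) to
be validated and prioritized. Both lists are plain `.csv`/`.tsv` files of
UniProt/SwissProt accessions, human or mouse.

## The scoring model

The evidence substrate is a set of *literature clusters*: groups of
proteins inferred to be functionally associated because their publication
records co-cluster under the Markov cluster algorithm (MCL, inflation
2.0). Each query–reference pair (q, r) is evaluated through a strict
four-tier hierarchy; the first satisfied tier assigns the score and stops
the search:

1. **InCluster** — q and r share a cluster: score **1**.
2. **Paralogue** — a paralogue of q shares a cluster with r: score **0.5**.
3. **Complex** — a complex partner of q shares a cluster with r: score **0.5**.
4. **Orthologue** — the orthologues of q and r share a cluster in the
   other species (human↔mouse): score **0.5**.

The *overall* score of a query is the sum of its pairwise scores over the
reference list; queries are ranked by overall score, descending. Proteins
outside every cluster were never analyzed and are reported in a separate
exclusion table. Significance of a query list's total score is assessed by
a permutation test: 1000 random query lists of the same size are drawn
from the clustered proteins of the species (minus the references) and
scored identically; the empirical p-value is
`(#{null ≥ observed} + 1) / (n + 1)`.

See `docs/methods.md` for the full model description, including the two
readings of the complex tier and the MCL numerical choices.

## Worked example

Generate a synthetic knowledge base with a planted module (2 queries per
tier plus 2 evidence-free queries, 10 references), then score and test it:

```sh
unired-rank synth kb --out-dir demo/fx --seed 4
unired-rank score --query demo/fx/query.csv --reference demo/fx/reference.csv \
    --kb demo/fx/kb.json --out-dir demo/results --permtest --n 1000 --seed 4
```

The run logs `analyzed 10 queries x 10 references; 8 evidence rows;
0 excluded` and writes four files. `scores.csv` is the ranked score
matrix — rows are query proteins labelled `ACCESSION (GENENAME)`, columns
the references, the last column the overall score in descending order:

```
query,P00301 (G301),P00302 (G302),P00303 (G303),...,Overall
P00311 (G311),1.0,,,...,1.0
P00312 (G312),,1.0,,...,1.0
P00313 (G313),,,0.5,...,0.5
```

The two in-cluster queries (score 1.0 with their reference) rank first,
followed by the paralogue/complex/orthologue queries at 0.5, then the
evidence-free queries at 0. `associations.csv` names the tier and the
mediating pair for every scored association — e.g. query P00313 reached
reference P00303 through its paralogue P00314:

```
query,reference,association_type,evidence_pair,score
P00311,P00301,InCluster,P00311|P00301,1.0
P00313,P00303,Paralogue,P00314|P00303,0.5
```

`permutation.json` reports the significance of the whole list:
`observed_sum 5.0`, `universe_size 314`, `p_value 0.000999` — the planted
list beats all 1000 random lists, so p sits at the estimator floor
1/1001, below 10⁻³.

Clusters can also be rebuilt from a weighted association graph:

```sh
unired-rank synth graph --n-blocks 3 --block-size 4 --out demo/edges.tsv
unired-rank cluster --edges demo/edges.tsv --out demo/clusters.tsv --inflation 2.0
```

## Input formats

Input lists: one or many accessions per line, comma- or tab-separated;
invalid tokens are rejected individually with a reason, duplicates
collapse. Knowledge-base source tables are headered TSVs (real
Ensembl/ComplexPortal exports must be converted to these columns first):

| table | columns |
|-------|---------|
| clusters | `cluster_id`, `accession` |
| paralogues | `protein_a`, `protein_b` (same species) |
| orthologues | `human`, `mouse` |
| complexes | `complex_id`, `accession` |
| id mapping | `accession`, `gene_name`, `ncbi_gene_name`, `ensembl_gene_id` (+ optional `<field>_reviewed`) |

`unired-rank build-kb` assembles these into the versioned JSON knowledge
base (top-level keys `version`, `species`, `records`, `clusters`,
`complexes`) that `unired-rank score` consumes.

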