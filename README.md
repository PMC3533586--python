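# ontosim

Knowledge-based semantic similarity and relatedness between concepts in a
taxonomy or semantic network.

`ontosim` builds a rooted, acyclic concept taxonomy from standard inputs
(tab-separated edge lists, OBO 1.2 ontologies, or a configurable
pipe-delimited relations table), precomputes depth and information content,
and exposes:

- **Path-based measures** — Path (inverse shortest-path node count), a
  unit-interval scaled Leacock–Chodorow, and the self-similarity-corrected
  Wu & Palmer.
- **Information-content measures** — Lin, the Jiang–Conrath distance, and
  IC reformulations of LCH and Path built on that distance.  IC can be
  *intrinsic* (computed from the taxonomy's leaf/subsumer structure alone)
  or *corpus* (from a raw concept-frequency table aggregated over
  descendant sets).
- **Personalized PageRank relatedness** — per-concept stationary probability
  vectors over an undirected concept graph (taxonomic edges only, or all
  relationships), scored pairwise by cosine.  Default damping factor 0.85.
- **Benchmark evaluation** — Spearman rank correlation of measure outputs
  against human-rated concept pairs, with Fisher r-to-z tests between
  correlations.

All similarity measures are symmetric, bounded to [0, 1], and score a
concept against itself as exactly 1.  No licensed vocabulary (UMLS,
SNOMED CT, MeSH) is needed to use or test the package: `ontosim.fixtures`
provides a frozen toy taxonomy, seeded random DAG generators, synthetic
benchmarks, and independent brute-force oracles.

## Command line

```sh
# build a taxonomy artifact from an edge list (child<TAB>parent[<TAB>label])
ontosim build --input edges.tsv --format edgelist --out graph.tax

# score pairs under several measures (intrinsic IC by default)
ontosim sim --input graph.tax --measure path --measure wupalmer --measure lin C1 C2
ontosim sim --input graph.tax --pairs pairs.tsv --measure lin --ic corpus --freq counts.tsv

# personalized-PageRank relatedness (raw graph input, not an artifact)
ontosim ppr --input edges.tsv --mode all --damping 0.85 C1 C2

# correlate measures against a rated benchmark (concept1<TAB>concept2<TAB>rating)
ontosim eval --input graph.tax --benchmark ratings.tsv \
    --measure path --measure lch-ic --compare

# emit synthetic demo inputs
ontosim fixtures --kind dag --seed 7 --n 30 --out demo.tsv
ontosim fixtures --kind benchmark --seed 7 --n 30 --n-pairs 50 --out bench.tsv
```

Measures: `path`, `lch`, `wupalmer`, `lin`, `jc` (a distance, not a
similarity), `lch-ic`, `path-ic`, and for `eval` also `ppr-taxonomy` /
`ppr-all`.

## Library sketch

```python
from ontosim import (build_taxonomy, intrinsic_ic, sim_lin,
                     build_ppr_graph, ppr_vector, ppr_relatedness)
from ontosim.fixtures import toy_T0

t = build_taxonomy(toy_T0())
ic = intrinsic_ic(t)
sim_lin(t, ic, "C", "D")            # 0.6309...

pg = build_ppr_graph(toy_T0(), mode="taxonomy")
ppr_relatedness(ppr_vector(pg, "C"), ppr_vector(pg, "D"))
```

## Notes and caveats

- Corpus IC normalizes aggregated frequencies by the root's total and caps
  zero-frequency concepts at the maximum finite IC; natural logarithms are
  used throughout.
- Frequency aggregation uses descendant *sets*, so concepts reachable by
  several parent paths are counted once.
- The Fisher r-to-z test is the independent-samples form; correlations
  computed on the same benchmark are dependent, so treat those p-values as
  approximate.
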