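# painnet

Graph-theory analysis of structural brain "pain networks" — directed,
weighted networks whose nodes are pain-related brain areas and whose
edges are axonal projections weighted by normalized projection volume
(segmented axonal signal in the target divided by injection-site volume,
the edge currency of mesoscale anterograde-tracing atlases).

It is written for systems neuroscientists who have a projection table
(source area, target area, hemisphere, experiment, volume) plus an area
catalog (acronym, name, anatomical group, injection coordinate) and want
the standard connectomic characterization of the resulting network:

* **graph construction** — replicate averaging, hemisphere combination,
  and an edge threshold (volumes < 0.01 are not considered connections);
* **topology** — density D = |E|/(|V|(|V|−1)), hop diameter,
  reciprocity, degree / closeness / betweenness centralities (Brandes),
  local clustering and degree assortativity on the undirected skeleton,
  degree histogram and Lorenz concentration curve, mean shortest-path
  distance over reachable ordered pairs;
* **community detection** — a from-scratch Walktrap (random-walk
  agglomeration with Ward-style merges, cut at maximal weighted
  modularity Q = Σ_c (w_c/W − (s_c/2W)²));
* **null models** — matched Erdős–Rényi G(n,m), Watts–Strogatz
  (mutual-directed, reciprocity 1 by construction) and Barabási–Albert
  (growth, reciprocity 0 by construction) comparison networks;
* **robustness** — error vs attack tolerance: remove a fraction f of
  nodes randomly or by repeatedly deleting the current highest-degree
  hub, tracking mean distance, largest-cluster fraction S, and mean
  isolated-cluster size ⟨s⟩ over 100 replicates;
* **spatial statistics** — inter-area Euclidean distances, classical
  (Torgerson) 2-D multidimensional scaling for layout, per-area
  log-strength vs distance correlations, and source/target
  projection-profile correlation matrices;
* **synthetic data** — a seeded generator of atlas-like projection
  tables (log-normal strengths spanning >1e5-fold, ipsilateral distance
  decay, calibrated 3.5:1 ipsi:contra volume ratio, planted communities,
  tunable reciprocity, right-skewed degrees) so the whole pipeline is
  testable without downloads.

All graph algorithms are implemented in the package itself; generic
graph libraries (networkx, igraph) are used only as independent oracles
in the test suite. See `docs/methods.md` for conventions and design
choices.

## Worked example

Generate a synthetic connectome and characterize it:

```sh
$ painnet simulate --seed 0 --out demo/
wrote synthetic connectome (49 areas) to demo

$ painnet metrics --projections demo/projections.csv --areas demo/areas.csv \
    --out demo/metrics.json
|V|=49 |E|=312 density=0.1327 diameter=4 reciprocity=0.519

$ painnet communities --projections demo/projections.csv --areas demo/areas.csv \
    --out demo/comm.json
35 communities, Q=0.4076
```

Reading the numbers: the thresholded graph keeps 312 of the 49·48
possible directed edges (density 13%), any area reaches any other in at
most 4 hops, and 52% of connections are reciprocated. The Walktrap cut
at maximal modularity (Q ≈ 0.41) splits this particular realization into
35 communities — many of them singleton peripheral areas, a consequence
of the generator's heavy-tailed strengths and degrees. `demo/metrics.json`
additionally holds the per-node centralities (e.g. top-3 by total degree
here: CH17, BS03, BS12), the degree histogram, and the Lorenz curve.

The same analyses run end to end from a YAML config (including
null-model comparison and robustness simulation):

```sh
painnet run --config run.yaml     # writes metrics.json, centrality.tsv,
                                  # communities.json, robustness.tsv,
                                  # distance/layout/correlation TSVs, run.log
```

with `run.yaml` like:

```yaml
projections: demo/projections.csv
areas: demo/areas.csv
out_dir: demo/report
edge_threshold: 0.01
null_model_reps: 50
robustness_reps: 100
seed: 0
```

The library mirrors the CLI: `build_graph`, `compute_metrics`,
`walktrap`, `erdos_renyi` / `watts_strogatz` / `barabasi_albert`,
`robustness_curve`, `pairwise_distances`, `mds_embed_2d`,
`generate_connectome`, `run_pipeline`, …

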