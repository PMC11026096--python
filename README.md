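# somamap

Somatotopic connectome analysis toolkit. Given EM-style neuron skeletons
(SWC), a predicted-synapse table and a neuron annotation table, somamap

- reads, validates, box-prunes and resamples skeletons (`somamap.skeletons`),
- scores pairwise morphological similarity on point/tangent clouds and
  clusters it with Ward linkage (`somamap.morphology`),
- filters synapses by cleft score, counts connections, aggregates edges and
  computes type-level connectivity normalized per possible directed edge
  (`somamap.connectivity`),
- clusters neurons by cosine similarity of their postsynaptic weight
  profiles, with per-edge synapse thresholds and cluster-composition
  reporting (`somamap.cosine_cluster`),
- assigns postsynaptic partners to their dominant-input type and builds the
  output-fraction-thresholded type → partner-group graph
  (`somamap.partner_graph`),
- classifies midline-crossing neurons and summarizes percent crossing per
  type (`somamap.laterality`),
- and generates a fully seeded synthetic somatotopic connectome with known
  ground truth for end-to-end validation (`somamap.synthetic`).

## CLI

Run the whole pipeline on generated data:

```sh
somamap run --synthetic --seed 42 -o out/
```

This writes the synthetic inputs (`out/inputs/`: per-neuron SWC files,
`synapses.csv`, `annotations.csv`, `ground_truth.json`), all intermediate
artifacts (similarity matrix, dendrogram in Newick, type connectivity,
partner graph, laterality tables) and a consolidated `out/report.json`
that includes recovery metrics (adjusted Rand index of the morphology and
connectivity clusterings against the generator's type labels, partner
assignment accuracy and laterality accuracy).

Run on your own data by pointing at a directory containing `swc/*.swc`,
`synapses.csv` (`pre_id,post_id,cleft_score,x,y,z`) and `annotations.csv`
(`neuron_id,type,nerve,side`):

```sh
somamap run -i data/ -o out/ --config config.yaml
```

Individual stages are exposed as subcommands: `generate`, `prune`,
`nblast`, `cluster`, `connectivity`, `cosine`, `graph`, `laterality`,
`evaluate`. See `somamap --help`.

Key defaults (all configurable via a YAML config, see
`somamap.config.PipelineConfig`): cleft-score filter keeps scores >= 50;
cosine analysis runs two passes — all types except the large sparse type at
a per-edge threshold of 7 synapses, and that type alone at a threshold of
3 (6 available as the `figure` preset); partner-graph edges are kept above
5% of a type's output; cluster composition is reported at the 20% level;
the midline is the plane x = 0 with strict inequality.

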