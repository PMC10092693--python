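# mitoquant

3D quantitation of fluorescently labelled mitochondrial networks in
confocal z-stacks — for cell biologists studying mitochondrial morphology
*in situ* (e.g. in pancreatic islet cells of living zebrafish larvae),
where networks range from fragmented (many short discrete units) to
filamentous (few, highly branched, interconnected components) and shift
between the two under stress, drug treatment and differentiation.

The pipeline: tubular (vesselness) enhancement and adaptive segmentation of
the mitochondria channel → topology-preserving 3D skeletonization → a
spatial skeleton graph whose nodes are tubule endpoints and junctions and
whose edges are tubules with metric (µm) lengths → per-cell network metrics.
For cells in clusters, a membrane channel is segmented into cells
(seeded watershed), each cell's mitochondria are extracted by mask +
background-noise injection, and 3D cell morphometry (volume, Feret
diameter) is joined to the network metrics.  A phantom generator produces
synthetic stacks with exact ground-truth geometry so the whole pipeline is
validated against known truth.

## Metrics

For a skeleton graph with nodes *N* (endpoints, degree 1; junctions,
degree ≥ 3), edges *E* (tubules, with length ℓ(e) measured along the
skeleton), and connected components *C*:

- total network length  L = Σₑ ℓ(e)  (µm)
- counts: |N|, |E|, |C|, free ends, 3-way / 4-way junctions
- average edge length  L / |E|
- average degree  ⟨k⟩ = Σᵢ kᵢ / |N|  (self-loops count 2)
- PHI = L(largest component) / L — 1.0 means a single connected network
- connectivity score (surrogate, pluggable):
  `conn_score = PHI × ⟨k⟩ × (L/|E|)`; a cell is called *fragmented* when
  the score falls below a threshold (default 3.0)

## Worked example

Generate a filamentous single-cell phantom and quantify it:

```sh
mitoquant phantom --out demo.tif --n-tubules 12 --seed 4
# phantom written to demo.tif (total truth length 46.33 µm)

mitoquant metrics --in demo.tif --out demo_out --sample-id demo
```

which prints the metrics row:

```json
{
  "sample_id": "demo",
  "total_length_um": 38.77,
  "n_components": 1,
  "n_nodes": 21,
  "n_edges": 24,
  "free_ends": 7,
  "junction3": 11,
  "junction4": 1,
  "avg_edge_length_um": 1.62,
  "avg_degree": 2.29,
  "phi": 1.0,
  "conn_score": 3.69,
  "phenotype": "filamentous_or_mild"
}
```

Reading: the 12 generated tubules fused into a single connected network
(one component, PHI = 1.0) with 11 three-way junctions; the recovered
skeleton length (38.8 µm) sits below the 46.3 µm ground-truth curve length
mainly because junction regions and blur-merged parallel passes shorten the
skeleton; the connectivity score 3.69 is above the 3.0 threshold, so the
cell is called filamentous.  `demo_out/` contains the binary mask (TIFF),
the skeleton as legacy-VTK polydata (loadable in any 3D viewer, coloured by
per-edge length), the graph as JSON, the metrics CSV and the resolved
configuration.

Other subcommands: `segment` (mask only), `skeleton` (mask → VTK),
`cells` (membrane → cell labels + morphometry CSV), `cluster` (full
per-cell analysis of a multi-cell stack), `stats` (t-test/ANOVA and
regression over a metrics table).  Equivalent library entry points live in
`mitoquant.pipeline` (`run_single_cell`, `run_cluster`).

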