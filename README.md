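# wholeheart

Desk-scale toolkit for **whole-heart cardiac activation simulation and
inverse potential mapping (IPM)**, aimed at computational
electrophysiology researchers who want a fast, fully synthetic test bench
for the two halves of a clinical ECG-imaging workflow:

1. **Simulation** — given a labeled tissue-volume model and a conduction
   system, compute when every mesh node activates and render isochronal
   maps, including the effect of virtual edema (slowed conduction) and
   transmural scar (complete conduction block).
2. **Inverse mapping** — given body-surface potentials (BSPs), reconstruct
   epicardial potentials and the activation sequence, and localize the
   earliest breakthrough.

Patient imaging and electrode recordings are replaced by programmatically
generated phantoms (slabs, concentric torso spheres, a simplified
two-chamber heart), so every result in the test suite is reproducible from
code alone.

## The models

**Tissue topology.** A segmentation is described by *patches* (facet
sets), *shells* (closed surfaces of patches) and *hulls* (tissue volumes
with uniform properties, bounded by one outer shell and optional hole
shells). `compile_topology` validates closure, consistent winding and
nesting before any physics runs.

**Activation: fastest route at fixed conduction velocities.** Nodes of
each conducting hull are joined by an edge when the straight segment
between them stays inside the hull (Möller–Trumbore ray/triangle tests
against the hull boundary); the edge travel time is distance divided by
the hull's conduction speed (myocardium 0.6 m/s, bundle branches 2 m/s,
edema 0.2 m/s, scar 0 m/s — values used unchanged as mm/ms). Activation
times are shortest-path times from the source(s) (Floyd–Warshall; a
single-source Dijkstra mode exists for large graphs), combined across
sources first-come-first-serve. Tissue-to-tissue propagation happens only
through interface nodes, which belong to both hulls.

**Potentials.** Every node gets a standard action-potential curve offset
by its local activation time; blocked nodes stay at rest.

**Forward/inverse.** A constant-collocation boundary element method on the
nested closed surfaces (epicardium, optional lungs at 0.04 S/m, thorax at
0.2 S/m) yields the transfer matrix **T** mapping epicardial to
body-surface potentials with an insulated body surface. IPMs are
reconstructed per time sample as

```
x = (TᵀT + λ²I)⁻¹ Tᵀ b,     λ = 0.01 by default
```

with an SVD filter-factor variant that agrees to 1e-8 relative.

## Worked example

Simulate a 60×10×10 mm myocardial slab with a transmural scar band and
compare against the healthy slab:

```sh
cat > scar.yaml <<EOF
phantom:
  kind: slab
  lesions:
    - region: {kind: box, lo: [25, -1, -1], hi: [35, 11, 11]}
      tissue: scar
output_dir: out
seed: 1
EOF
wholeheart phantom -c scar.yaml
wholeheart simulate -c scar.yaml
```

prints (reformatted):

```
{"n_nodes": 117, "percent_blocked": 53.8, "max_activation_ms": 47.9, ...}
```

53.8 % of nodes are blocked: the 10 mm scar spans the whole cross-section,
so every node distal to it (plus the scar interior) is unreachable — a
complete conduction block. The healthy slab reports `percent_blocked: 0`
and a far-corner arrival of 102.7 ms (= √(60²+10²+10²)/0.6). The full
chain

```sh
wholeheart roundtrip --seed 7
```

builds the two-chamber heart in a spherical torso, simulates sinus-rhythm
activation from the sinus-node analog, projects to 65 electrodes, adds
30 dB noise, inverts at λ = 0.01 and reports

```
{"localization_error_mm": 5.196, "mean_edge_length_mm": 3.695, ...}
```

i.e. the earliest reconstructed breakthrough lands 5.2 mm (about 1.4 mesh
edges) from the true source node.

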