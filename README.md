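# modnet

Knowledge-informed graph analysis of domain-specific brain network systems.

Most graph-theoretic fMRI studies either analyze whole-brain networks
data-driven (clustering, ICA) or restrict themselves to seed-based
connectivity. `modnet` implements the middle road: functional modules are
*predefined* from neuroanatomical knowledge (Brodmann areas grouped per
hemisphere into a four-level hierarchy, e.g. the language system's ten
fine-grained modules up to one whole-domain module), and graph metrics are
then computed for each module in two complementary ways on a whole-brain
binary connectivity graph:

- **local** metrics on the subgraph induced by the module's nodes —
  within-module integration;
- **global** metrics on the full graph, averaged over the module's nodes —
  the module's integration with the rest of the brain.

This lets a task contrast (e.g. word comprehension vs. word generation) be
tested per module and per hierarchy level, separating "this circuit became
internally denser" from "this circuit coupled more with everything else".

## What is implemented

- **Module atlas** — parcel centroids from a labeled NIfTI volume, Brodmann
  labeling by centroid lookup, anterior/posterior splits at the median *y*
  per hemisphere, hierarchical module assignment driven by a YAML
  specification (the language system ships with the package), and internode
  distance reports.
- **Preprocessing** — framewise displacement (Power convention, 50 mm
  rotation radius), scrubbing above 0.5 mm with one back / two forward
  neighbors, nuisance regression (6 motion + CSF + WM + first derivatives),
  discrete-cosine high-pass at 0.008 Hz. Censored volumes are dropped, never
  interpolated.
- **Connectivity** — Pearson correlation over retained volumes, optional
  partial correlation controlling the global signal, global FC (mean
  correlation), and relative-threshold binarization (top 20/30/40% of pairs,
  deterministic tie-breaking, nested edge sets).
- **Graph metrics** — degree density, shortest path length, clustering,
  nodal efficiency, betweenness (Brandes, unnormalized), eigenvector
  centrality, assortativity (local only), participation coefficient (global
  only); all written directly against explicit conventions and verified
  against brute-force oracles and networkx in the test suite.
- **Inference** — paired t tests, a linear mixed-effects model
  `value ~ module * task (+ global_fc)` with a by-subject random intercept,
  Benjamini–Hochberg FDR, node-randomization nulls (pseudofunctional modules
  on a group-template graph) and subject-level bootstrap of resting
  connectivity.
- **Synthetic data** — a multi-subject two-task generator with
  module-structured coupling, shared global signal, between-subject jitter,
  and motion spikes; every expected correlation has a closed form, so
  parameter recovery is checkable against ground truth.

## Worked example

Generate the default double-dissociation study (a motor-like module couples
more strongly during generation, a sensory-like module during
comprehension), compute local density at a 30% threshold, and test the
Task × Module interaction:

```python
import modnet as mn
from modnet.simulate import recovery_config

ds = mn.generate_dataset(recovery_config(seed=1, n_subjects=12))
table = mn.metric_table(ds, 0.3, modes=("local",), metrics=("degree_density",))
res, contrast = mn.interaction_test(
    table, "degree_density", ["Motoric language L", "Word recognition L"])
print(table[table["module"].isin(["Motoric language L", "Word recognition L"])]
      .groupby(["module", "task"])["value"].mean().round(3))
print(f"interaction t = {res.interaction_t:.2f}, p = {res.interaction_p:.2e}")
```

```
module              task
Motoric language L  wc      0.469
                    wg      1.000
Word recognition L  wc      1.000
                    wg      0.461
Name: value, dtype: float64
interaction t = -17.91, p = 1.03e-71
```

The cell means show the designed crossover — the motor module is internally
dense during word generation (`wg`), the word-recognition module during
comprehension (`wc`) — and the mixed model detects the interaction.

The same stages are available from the shell:

```bash
modnet simulate --config sim.yaml --seed 4 --out data/
modnet preprocess --ts data/sub-00_task-wc_ts.tsv \
    --motion data/sub-00_task-wc_motion.tsv \
    --confounds data/sub-00_task-wc_confounds.tsv --tr 2.0 --out clean.tsv
modnet connect --ts clean.tsv --threshold 0.3 --out graph.tsv
modnet atlas --parcellation parc.nii.gz --ba-map ba.nii.gz --out nodes.tsv
modnet metrics --graph graph.tsv --nodes nodes.tsv --level 1 --out metrics.tsv
modnet run --config study.yaml --out results/
```

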