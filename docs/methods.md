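# Methods

## Model and procedure

`modnet` analyzes task-dependent integration of predefined functional
modules in whole-brain connectivity graphs. The procedure per subject and
task condition is:

1. **Node time series** (nodes × volumes) are denoised: volumes with
   framewise displacement above a threshold are censored together with
   neighbors, the series are residualized against nuisance regressors, and
   slow drifts are removed with a discrete-cosine basis.
2. **Connectivity** is the Pearson correlation of the denoised series over
   retained volumes, optionally as a partial correlation controlling the
   global signal.
3. **Binarization** keeps the top proportion (default 30%) of node pairs
   by signed correlation as unweighted edges.
4. **Module metrics** are computed per functional module in two modes:
   *local* (metric computed on the module-induced subgraph, averaged over
   its nodes) and *global* (metric computed on the whole graph, averaged
   over the module's nodes).
5. **Inference** compares metrics across conditions with paired t tests
   and a linear mixed-effects model
   `value ~ module + task + module:task (+ global_fc)` with a by-subject
   random intercept; multiple cells are corrected with Benjamini–Hochberg
   FDR. Two null models gauge specificity: pseudofunctional modules of
   matched size drawn at random from a group-template graph, and a
   subject-level bootstrap of resting connectivity matrices.

The module hierarchy is data, not code: a YAML file lists, per level,
module names, hemisphere scope, and members (Level 1 as Brodmann areas
with optional anterior/posterior qualifiers; higher levels as unions of
Level-1 modules). The packaged language specification defines five
Level-1 module families per hemisphere (word recognition, semantic,
syntactic, auditory, motoric), six Level-2 modules, one Level-3 module per
hemisphere and one Level-4 module. The semantic module feeds two Level-2
modules, so Level-2 membership is a set. The composition follows the
descriptive text of the source literature, under which the syntactic
module has no Level-2 parent; membership at Levels 3–4 is unaffected.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| FD threshold | 0.5 | mm | standard motion-scrubbing cutoff |
| scrub window | 1 back / 2 forward | volumes | motion artifacts bleed into neighboring volumes |
| rotation radius | 50 | mm | converts radians to arc length on a head-sized sphere |
| high-pass cutoff | 0.008 | Hz | removes scanner drift while sparing task fluctuations |
| threshold proportion | 0.3 (0.2, 0.4 for sensitivity) | — | relative thresholds equalize edge counts across conditions whose global FC differs |
| ranking | signed correlation | — | a strongly negative correlation is not strong connectivity; `abs` ranking available |
| betweenness | unnormalized | — | raw pair-dependency sums; normalization by (n−1)(n−2)/2 available |
| null replicates | 10,000 | — | default for production runs; tests use smaller R |

## Numerical conventions

- **High-pass as DCT regression.** All discrete-cosine components with
  frequency below the cutoff (plus an intercept) are regressed out over
  retained volumes. Unlike an IIR filter, this remains well-defined on
  censored series; censoring is listwise and censored samples are zeroed
  and excluded downstream.
- **Confound derivatives** are backward differences with a leading zero.
  Collinear confound columns are dropped (QR with pivoting) with a warning.
- **Thresholding** rounds the edge count half-away-from-zero and breaks
  ties at the cut lexicographically by (i, j), which makes edge sets
  deterministic and nested across proportions.
- **Disconnected pairs** are excluded from shortest-path means; nodal
  efficiency uses 1/∞ = 0. A fully isolated node has undefined path length
  and is excluded from the module mean with a warning; its density,
  clustering, efficiency and betweenness are 0.
- **Eigenvector centrality** is the nonnegative leading eigenvector of the
  largest connected component (power iteration on A + I so bipartite
  components converge; relative tolerance 1e−10), zero off-component.
- **Assortativity** is undefined (NaN) when endpoint degrees have zero
  variance (regular graphs).
- **Participation coefficient** needs a community partition; the package
  uses the chosen hierarchy level's modules plus one catch-all community
  for unassigned nodes. This is an assumption — other partitions are
  accepted via the `community` argument.
- **Anterior/posterior splits** compute the median y per hemisphere from
  the BA map's voxels by default (`map_voxels`), or from member-node
  centroids (`member_nodes`); nodes strictly above the median are anterior,
  ties go posterior. Both references are exposed because either reading is
  defensible; the choice is recorded in output metadata.
- **Empirical p-values** use the add-one rule, (r + 1)/(R + 1), so they are
  never zero; two-sided p doubles the smaller tail, capped at 1.
- **Mixed-model fits** use REML via statsmodels MixedLM; Wald z p-values.
  Singular random-effects fits are retried with L-BFGS and flagged.

## The synthetic-data generator

Node *i* in module *m* under task τ is generated as

    x_i(t) = √c · s_m(t) + √ρ · h(t) + √b · g(t) + √(1 − c − ρ − b) · ε_i(t)

with unit-variance independent Gaussian latents: s_m shared within the
module, h shared by all module nodes (weight ρ, default 0), g a global
signal shared by every node (weight b, default 0.1), ε idiosyncratic.
Expected correlations are c + ρ + b within a module, ρ + b across modules,
and b against unassigned nodes — closed-form ground truth for every pair.
The coupling c is jittered per subject (multiplicative, 10% SD), giving
the mixed model's random intercept real between-subject variance to
absorb. Motion spikes, when enabled, enter both the motion parameters
(1 mm translation jumps, crossing the 0.5 mm FD threshold) and the data
(additive global transients), so scrubbing measurably improves agreement
with the expected correlations.

**Default study conditions.** 20 subjects × 2 tasks, 80 nodes, 200 volumes
at TR 2 s. Two 10-node task-modulated modules form a double dissociation
(coupling 0.15 vs 0.45 crossed over tasks) against two independent 30-node
task-invariant background systems (coupling 0.3). The background layout is
deliberate: a structureless background would leave every within-module
pair far above a 30% relative threshold (local density saturates at 1),
and a single background system would make the threshold cut move both
task modules' densities together, inflating the mixed model's residual
relative to the interaction contrast. Two independent background systems
keep edge competition at the cut while keeping the metric-level errors
close to the model's assumptions; with this design the interaction test
is calibrated (type-I error ≈ 5%) and the designed effect is detected
essentially always at these sample sizes.

What the generator does **not** emulate: hemodynamic smoothness is off by
default (white latents; an AR(1) option exists), there is no spatial
structure or image support, no task-block activation, and correlation
heterogeneity within a module is minimal (single shared latent per
module). Passing tests therefore demonstrate the pipeline's statistical
machinery under a favorable, analytically tractable model — not
performance on real BOLD data.

## Null models

The node-randomization null draws pseudofunctional modules of matched size
uniformly from the template graph; the expected local density of a random
induced subgraph equals the template's density, which the test suite
verifies on an Erdős–Rényi template. The bootstrap resamples subjects with
replacement, averages matrices into a template, thresholds, and recomputes
true-module metrics; the bootstrap SE matches a fresh-replication
Monte-Carlo estimate of the sampling SD. A subject-level **jackknife** is
*not* a valid variance oracle for these statistics: they count edges
crossing a relative-threshold cut, a non-smooth functional for which the
jackknife is inconsistent — in our measurements it overestimates the
sampling SD by 30–50%.

## Problem sizes

Test and acceptance computations use the generator's default conditions
(20 subjects, 80 nodes, 200 volumes), 100 replicates for the detection and
type-I rates, 2,000 replicates for the Erdős–Rényi null, and 1,000 random
graphs of ≤ 8 nodes for the brute-force oracle sweep. These sizes were
chosen so the whole suite reruns in a few minutes while keeping Monte
Carlo error small relative to the asserted tolerances; production null
models default to 10,000 replicates.

## Known limitations

- Brodmann labeling uses nearest-voxel lookup of the node centroid — a
  node straddling an areal boundary is assigned by its center only.
- The hierarchy assumes BA-based modules; surface parcellations and
  probabilistic maps are out of scope.
- The LMM treats module metric values as homoskedastic across cells;
  strongly saturated cells (density pinned at 1) violate this and are a
  sign the threshold/coupling regime, not the model, should change.
- CSF/WM nuisance signals are accepted as given columns; extracting them
  from images (and all spatial preprocessing) is out of scope.
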