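# Methods

This note documents the models, defaults and numerical choices behind the
whisker-connectome pipeline, in the order the stages run.

## Data model

An *experiment record* is one anterograde tracing experiment: an injected
source structure, the transgenic line of the animal, the injection
hemisphere, and — for every structure in both hemispheres — four projection
summaries: density (fraction of expressing pixels, in [0, 1]), intensity
(summed brightness, a.u.), energy (brightness per pixel, a.u.) and volume
(mm³ of labeled signal). The ontology is a flat, ordered structure list
mirrored across hemispheres; literature synonyms (`SSp-bfd`/`bfd`,
`M1`/`MOp`, `nRT`/`RT`, `PoM`/`PO`) resolve through an alias table. Panels
are configuration: an 18-nucleus core (the classical whisker sensorimotor
set), a 57-nucleus extended network, and the neuromodulatory subset
`{VTA, LC, DR, TM, PPN, SI}` used in the ablation comparison. The shipped
57-entry list contains the core plus every nucleus named in the hub/density
narratives and plausible Allen-style fillers with anatomical groups; the
shipped 34-pair reference list is a documented placeholder over the core
panel drawn from classical lemniscal/paralemniscal/descending pathways —
both are meant to be replaced by users with their own curated lists.

## Injection specificity and the two gates

Two estimators on an injection-density grid `I ≥ 0` paired with a binary
structure mask `M` of identical shape:

- binarized: `|{v : I(v) > 0 ∧ M(v) = 1}| / |{v : I(v) > 0}|` — invariant
  under any strictly monotone positive transform of the densities;
- weighted: `Σ I·M / Σ I` — invariant under uniform rescaling.

The binarized estimator feeds the *inclusion* gate (keep experiments with
`s ≥ 0.50`); the weighted estimator feeds the *confirmation* tier
(`s ≥ 0.75`). Both boundaries are inclusive (≥): an experiment exactly at
the cut survives. The mapping of estimator to tier is fixed but overridable
per call (`threshold=` argument). The source phrasing that mixes the
"masked" and "binarized" quantities is resolved here as the two clean
estimators above. Records may carry a precomputed `{binarized, weighted}`
pair (the synthetic generator writes one); otherwise the pair is computed
from the paired volume/mask rasters. Volumes are plain dense 3-D rasters
serialized as JSON with a header-declared shape.

## Matrices and hemisphere merge

Experiments are grouped per line; each injected source contributes a row of
an S×2S matrix per variable, with the column blocks ordered ipsilateral /
contralateral *relative to the injection side* (sources are indexed by
structure regardless of injected hemisphere). Repeat injections at the same
source combine by elementwise **maximum** — the false-negative-averse choice
consistent with the downstream max-merge — with a `combine="mean"` flag
available. The two hemispheric blocks merge by elementwise maximum, because
contralateral projections are sparse and a union keeps them. Rows for
never-injected structures are flagged *unmeasured* and propagate as
"no data" (never "no connection") through binarization, classification and
density profiling.

## Threshold calibration

Detection is `value ≥ θ`. Under that convention, "raise the threshold until
a reference connection is lost; keep the last value with 100 % recall" has
the closed form `θ_v = min over reference edges of variable v` on the
wild-type merged matrices. `calibrate()` computes that minimum exactly; a
`method="sweep"` mode reproduces the incremental narrative on a grid for
audit (it approaches the closed form from below). Calibration is infeasible
— and raises, naming the edge and variable — if any reference edge lies in
an unmeasured row or has a zero value on any variable. Thresholds calibrate
on wild-type data only and are then applied unchanged to every line. The
`allen2024` preset (density 9e-5, intensity 222 a.u., energy 28.91 a.u.,
volume 0.0395 mm³) ships for users of real atlas exports who skip
calibration; it is data-dependent and deliberately untested against the
synthetic generator.

Consequences tested as properties: every reference edge survives
binarization at the calibrated thresholds; raising any θ to the next larger
observed value on its variable loses at least one reference edge
(tightness); raising thresholds only removes edges (monotonicity).

## Classification

Per-category maps are elementwise ORs of the per-line binary connectomes
(wild is a first-class category, so wild-only edges are representable); the
"all" map is the OR over categories. Each detected off-diagonal edge gets
one status: `known` (in the curated literature list), `confirmed_new`
(source backed by a ≥75 %-weighted-specificity gated experiment) or
`putative_new`. Confirmation support for an undetected edge logs a warning
and is otherwise ignored. Coverage is reported against n² ordered pairs —
the field's customary denominator, which counts the self-pairs that are
never counted as connections — with the off-diagonal figure (n(n−1)
denominator) alongside. Display percentages are *truncated* to one decimal
(157/324 → 48.4), matching how such coverage figures are conventionally
printed; the raw fraction is also emitted.

## Graph analysis

All metrics are computed on the binary directed graph with the diagonal
dropped (weighted analyses are out of scope). Definitions and conventions:

- degree centrality DC = in-degree + out-degree; Σ DC = 2·edges.
- clustering: Fagiolo's directed clustering coefficient (networkx's
  directed `clustering`), covering all triangle orientations.
- shortest path: per node, the mean geodesic to *reachable* nodes;
  unreachable pairs are excluded from the mean, and a node reaching nothing
  scores 0. (Printed mean shortest paths below 1 in the connectomics
  literature come from toolbox-specific normalizations; this package keeps
  standard unweighted geodesics, whose per-node means are ≥ 1 whenever an
  edge exists.)
- efficiency: mean inverse geodesic over the other n−1 nodes, unreachable
  pairs contributing 0; local efficiency: efficiency of the subgraph induced
  by a node's combined in/out neighbourhood (0 with fewer than 2
  neighbours); betweenness: normalized by (n−1)(n−2).
- hubs: DC strictly above mean + one *population* standard deviation
  (strict inequality makes regular graphs hub-free; ddof is configurable by
  passing a different series to `detect_hubs`).
- group shares: Σ of DC within an anatomical group over 2·edges — the
  fraction of connection endpoints incident to that group.

The ER null is the exact-edge-count model G(n, M) (not independent-edge
G(n, p)): each draw has exactly the observed number of edges, no self-loops,
seeded. The small-world verdict compares the graph's mean nodal clustering
and mean nodal shortest path against the averages over `n_null` seeded
draws; the verdict requires strictly higher clustering *and* strictly lower
path, so ties fail.

The neuromodulator-ablation comparison is a pooled two-sample permutation
test: the nodal metric vector on the full graph (length n) and on the
induced subgraph without the removed nuclei (length n−k) are pooled and
re-split at their original sizes `n_perm` times (default 10,000); the
statistic is |mean difference| and p = (#{null ≥ observed} + 1)/(n_perm+1),
so p ≥ 1/(n_perm+1) and the empty-removal case gives p = 1. A tiny absolute
tolerance (1e-12 scaled) guards tie counting against float summation order.
Permutations are vectorized (argsort of uniform draws), seeded through
`numpy.random.default_rng`.

## Density profiles

Per source, the continuous density row (diagonal excluded) is normalized to
sum to 1 and sorted descending; top-k values are cumulative shares, clipped
at the target count. By default the row is first restricted to edges
retained in the binarized map so sub-threshold background cannot dilute the
shares (pass `detected=None` to profile the raw row). Sources that are
unmeasured or have zero outgoing density are listed under an explicit
"no data" marker. Profiles are scale-invariant in the row, and majorization
of sorted shares implies pointwise top-k dominance (checked by brute force
in the tests). The caption/text disagreement about "incoming" vs "outgoing"
in the source material is resolved as *outgoing*, matching the per-source
normalization.

## Synthetic generator

The generator emulates the statistical shape of the tracing data, not its
biology: no topographic structure, no realistic projection motifs. Defaults
(chosen once as the test-scale study conditions):

- 30 structures per hemisphere (723 supported; the core-18 acronyms occupy
  the first slots, fillers carry cycling anatomical groups);
- planted directed adjacency with edge probability 0.15 and per-edge
  strengths in (0, 1]; 34 reference edges forced among core-panel pairs;
- lines: wild type plus 2 excitatory, 2 inhibitory, 1 uncategorized line;
  wild type injects every source (two experiments each, one of which is
  guaranteed past the inclusion gate so calibration is always feasible);
  transgenic lines each cover 70 % of sources;
- separable signal model: on true edges every variable is drawn in
  [floor, scale] as `floor + strength·(scale − floor)·u`, `u ∈ (0, 1]`;
  on non-edges uniform in [0, ceiling] with ceiling < floor
  (density 0.005 < 0.02, intensity 10 < 50, energy 1 < 5, volume
  0.002 < 0.01 mm³). Reference edges in wild-type experiments are written
  *exactly at the floor*, which makes the calibration answer analytic
  (θ = floor per variable) and end-to-end recovery exact;
- contralateral expression of a true edge with probability 0.2 (reference
  edges excepted, to keep the calibration floor exact under the max-merge);
- injection specificity drawn from a three-band mixture (mass 0.30 below
  0.50, 0.35 between the gates, 0.35 above 0.75); each experiment gets a
  16³ voxel grid whose mask is a half-space and whose injection support is
  200 voxels with the in-mask count set to `round(s·K)` — realizing the
  binarized target within 1/(2K), far inside the ±0.02 requirement, with
  the weighted value computed from the drawn voxel densities. (A geometric
  blob placement was considered and rejected: discrete sphere/plane
  intersections cannot guarantee the tolerance; exact voxel counting can.)

`degrade(bundle, overlap)` re-draws `ceil(overlap · edges)` planted edges
(reference edges included) into the background range in every experiment.
Because a degraded bundle may lose reference edges, recall under degradation
is scored at fixed thresholds equal to the planted floors — the calibration
answer on the undegraded bundle — under which recall falls from 1 (overlap
0) to 0 (overlap 1), strictly monotonically in the separable regime.

What passing tests show — and what they do not: exact recovery in the
separable regime validates the *logic* of gating, calibration, consensus
binarization and classification, and the degradation mode shows graceful
recall loss. Real tracer data are not separable (signal and background
overlap, per-structure noise is heteroscedastic, projections are
topographically correlated), so pipeline performance on real atlas exports
is an empirical question these tests do not answer.

## Pipeline, determinism and sizes

Stage order is fixed: specificity → inclusion gate → per-line matrices →
hemisphere merge → panel extraction → calibration (or preset/explicit
thresholds, which skip it) → consensus binarization → category combination →
confirmation support → classification (core panel) → graph report, ablation
permutation tests and small-world verdict (extended panel) → density
profiles. The density matrix for profiling is the elementwise max over the
per-line merged density matrices. Every stage is a pure function of inputs
plus seed; the disk runner writes a manifest of SHA-256 content hashes, and
a re-run with identical config reproduces them exactly. Errors halt with
the stage name and offending identifiers.

Default problem sizes in the shipped tests and the acceptance script — 20–30
structures per hemisphere, 8³–16³ voxel grids, 50–1,000 null draws,
200–2,000 permutations per test — were chosen as the smallest scales at
which every property under test is non-trivially exercised; all scale up by
configuration.

## Known limitations

- No image processing, registration or atlas alignment: volumes and masks
  must already share a voxel space, and the anatomical-confirmation tier is
  a specificity-derived flag, not an image-verified one.
- No weighted-graph metrics, no HTTP client for live atlas downloads.
- The shipped reference and literature lists are placeholders; scientific
  use requires curated replacements.
- The 723-structure full parcellation is supported but not the default;
  generator cost grows quadratically with structure count.
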