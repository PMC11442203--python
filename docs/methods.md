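# Methods

## Model

`cellfp` treats pharmacological similarity between compounds as
similarity of *cellular function fingerprints* on a tripartite
heterogeneous network with compound, protein-target and function-term
nodes.  Two edge layers connect them: scored compound→target prediction
edges (structure-based target prediction confidence, BATMAN-TCM-style)
and unscored target→term annotation edges (GO-BP / Reactome / KEGG /
WikiPathways gene sets).  The working assumption is that two compounds
with similar term profiles perturb similar biology even when their
targets differ, which is what makes herbal components comparable to
marketed drugs whose targets rarely overlap exactly.

The fingerprint of compound c is row c of the path-count matrix
M[c, p] = |{t : (c, t) ∈ E_ct ∧ (t, p) ∈ E_tp}|.  Similarity is PathSim
along the symmetric meta-path compound→target→term→target→compound:
with P = M·Mᵀ,

    s(x, y) = 2 P[x, y] / (P[x, x] + P[y, y])

and distance d = 1 − s.  P is computed in int64 and only the final
division is floating-point, so s is exactly reproducible and the test
suite can demand bit-identical agreement with a brute-force path
enumeration.

Assumptions worth stating: edge confidence scores gate edge inclusion
but do not weight paths (no weighted-PathSim variant); annotation terms
are treated as a flat vocabulary (no GO-graph ancestor propagation); and
all annotation sources are pooled into one fingerprint by default, with
per-source fingerprints available via `path_count_matrix(...,
source_filter=)`.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `score_threshold` | 20 | strict ">" cutoff on compound–target confidence; both 10 and 20 are defensible readings of upstream target-prediction practice, so it is a config key, never hard-coded |
| `fingerprint_mode` | `count` | `count` uses true path counts; `binary` uses 0/1 compound–term incidence (a set-based "fingerprint" reading); reported results should state the mode |
| `linkage` | `complete` | agglomeration criterion; complete is the conventional default for this kind of drug clustering, the others (average, single, ward) are available |
| `k_main` | √n heuristic | number of dendrogram groups; there is no principled automatic choice here, so pipelines should set it explicitly (the worked-example bundle pins 7) |
| `k_filter`, `min_cosize` | off, 2 | drug-library consistency screen: cluster drugs alone, cut at `k_filter`, drop groups smaller than `min_cosize` |
| `threshold_mode` | `global_median` | screen threshold: median of all component × drug cross distances, or `fixed` with `threshold_value`; comparison is strictly "<" |
| `atc_level` | 3 | ATC truncation level (1–5) for code comparison; level 3 (pharmacological subgroup) matches the granularity of coarse drug-class arguments |
| `tau` | 0.5 | direction-call threshold on mean signature z; scores in (−tau, tau] are *flat* |
| `min_overlap` | 3 | minimum term-gene ∩ signature-gene overlap for a call; below it the result is a *no-call*, which is reported distinctly from flat |
| `nearest_floor` | 0.0 | minimum similarity for a component to inherit mechanism from its nearest drug |

## Numerical and procedural choices

- **Path-less compounds** (no compound–target–term chain) would make
  s(x, x) = 0/0; they are defined to have similarity 0 to everything,
  themselves included, and are logged.  This keeps them maximally
  distant rather than undefined, matching their exclusion from
  downstream screens.
- **Clustering** is an explicit Lance–Williams agglomeration rather than
  a scipy call, because the pipeline promises deterministic, specified
  tie-breaking: among equal-distance cluster pairs, the pair whose
  (smallest member id, second representative) sorts lexicographically
  first merges.  On tie-free matrices it coincides with
  scipy.cluster.hierarchy, which the tests use as an independent oracle
  for all four linkages.  Ward runs on squared distances via the usual
  update formula and reports heights on the distance scale.  O(n³) cost
  is irrelevant at the few hundred compounds this handles.
- **Group labels** are numbered by first appearance along the canonical
  leaf order (at each internal node the child holding the
  lexicographically smallest leaf is drawn first), so "group 1..k" is
  reproducible across runs and platforms.
- **Median threshold**: even-count cross-distance sets take the mean of
  the central pair.  The screen uses strict "<", so a drug exactly at
  the threshold is excluded — the boundary case is pinned by a test.
- **Duplicate compound–target rows** keep the maximum score: re-exported
  prediction files then never lose edges.
- **Coverage ratios**: both m/M over function terms and g/G over cluster
  groups are computed and reported side by side; the two are genuinely
  different statistics that coarse verbal descriptions of "coverage"
  tend to conflate, and neither is silently preferred.  CombinedRatio is
  the exact arithmetic mean of the ATC, term and drug ratios.
- **Direction scoring** is the mean signature z over a term's genes,
  thresholded at ±tau, and group-level direction is the mean of member
  scores thresholded at the same tau.  This rule was chosen for
  transparency and testability over enrichment-style statistics
  (KS-based connectivity scores are out of scope); it is antisymmetric
  under sign flips of the signature, which is asserted exactly.

## Synthetic data: what it emulates, what it does not

The generator plants K mechanism groups.  Each compound gets
`n_targets_per_compound` private targets whose annotations land
round-robin in the group's GO-BP term pool with probability
1 − `noise_rate`, else uniformly on out-of-group terms (other pools or a
Reactome-flavoured shared background).  Drugs carry one level-3 ATC
family per group; indications span `groups_per_indication` groups;
signatures are i.i.d. Gaussian (sd `signature_noise_sd`) plus ±
`signature_shift` on each group term's gene set, one planted sign per
(group, term).  Defaults — K = 4 groups, 3 components + 6 drugs per
group, 8 targets per compound, 8 terms per group, 12 background terms,
noise 0.1, shift 2 on sd-1 noise — are sized so that planted structure
is recoverable but not trivially so, and they match the regimes the
recovery checks run under (noise 0 and 0.1; shift 2 vs tau 0.5 with ≥10
genes per term).

Deliberate departures from real data: targets are private to compounds
(real drugs share targets — similarity here flows only through shared
*terms*, which is exactly the quantity PathSim measures); term pools are
disjoint across groups at noise 0 (real GO terms overlap heavily and sit
in a DAG); score distributions are uniform, not BATMAN-TCM-like; and
signatures have no cell-line or dose structure.  Passing tests therefore
demonstrate correctness of the arithmetic and the recovery behaviour of
the method under its own assumptions — not performance on real
pharmacological databases, where annotation correlation and promiscuous
targets will blur group boundaries well before `noise_rate` suggests.

The **worked-example fixture** is a deterministic construction, not a
draw: 7 groups with 10-term pools, one component per group covering 4
pool terms, 32 drugs of which per-group 4/4/4/3/3/3/2 cover all 10 terms
(distance to the component 1 − 8/14 = 3/7 < 0.53) and the rest cover
terms 2–9 (distance 1 − 4/12 = 2/3 ≥ 0.53).  Screening at the fixed
threshold 0.53 yields exactly 23 of 32 similar drugs across all 7
groups, i.e. drug coverage 0.72 and group coverage 1, end to end through
file I/O, similarity, clustering and screening.  The fixture's
cross-distance distribution is three-valued, so its own global median
would be 1.0; the fixture therefore carries the fixed threshold in its
emitted config, while global-median behaviour (below-threshold fraction
0.5 on continuous distances) is exercised on random matrices.

## Problem sizes

The test suite and the acceptance script run entirely on generated
data: oracle equivalence on 100 networks of ≤8 compounds × ≤10 targets
× ≤6 terms; clustering recovery on 36-compound networks over 20 seeds;
direction recovery on 100 seeded instances of a 2-group, 16-compound
design (1,200 group × term calls); a 30 × 40 cross-distance screen.
These sizes give exact or near-degenerate expected outcomes for the
deterministic checks and comfortable statistical margins for the
stochastic ones, while a full run stays in the seconds range.

## Known limitations

- No weighted PathSim (edge scores gate, never weight), no learned
  embeddings, no bootstrap/consensus clustering, no automatic k
  selection, no permutation null for coverage significance.
- Gene identifiers are taken as opaque symbols; cross-namespace ID
  mapping is out of scope.
- Term ids must be globally unique across annotation sources (true for
  real GO/Reactome/KEGG/Wiki accessions, which are disjoint
  namespaces).
- The regulation-direction rule aggregates one signature per drug; if a
  drug has several (cell lines, doses) they must be reduced to one
  profile upstream.
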