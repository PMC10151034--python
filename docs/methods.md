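# Methods

## Graph model

Entities are CURIE-identified and typed from a closed set: drug, protein,
gene, disease, process. Assertions are single-provenance interaction
records (the in-memory equivalent of one nanopublication: assertion +
supporting provenance + attribution; the optional TriG export materialises
exactly those three named graphs per record). Edges are unique per
(subject, interaction type, object) triple and own every record asserting
that triple; a triple seen with two interaction types yields two edges.

Directionality is per edge class, not per query: protein–protein
interaction records are stored undirected (most detection methods do not
orient the interaction), while drug→target and gene→disease assertions are
directed. Traversal respects this: a directed edge can only be crossed
along its direction (or against it when expanding over incoming links),
an undirected edge can be crossed either way. Records for one triple must
agree on directedness; a conflict is a validation error rather than a
silent coercion. Self-interactions are stored but never advance a path.

Identifier collisions across sources (BRAF arriving as an interaction
partner and as a disease gene) resolve by first registration wins, with
the count logged; the gene/protein distinction is deliberately soft since
the sources themselves conflate gene symbols and protein accessions. A
config-driven synonym map normalises source-specific identifiers before
insertion; there is no fuzzy matching, by design, so ingestion is
reproducible byte for byte.

## Evidence model

Probabilities are assigned per record, not per edge:

| evidence                        | probability (default) |
|---------------------------------|-----------------------|
| manually curated source         | 0.999                 |
| experimental, method level 3    | 0.99                  |
| experimental, method level 2    | 0.95                  |
| experimental, method level 1    | 0.8                   |

The method-code → level table is data (YAML), not code. The full expert
rating covered on the order of a hundred PSI-MI detection methods; the
shipped default is a small illustrative subset (`MI:0018` two-hybrid → 1,
`MI:0096` pull-down → 2, `MI:0114` X-ray crystallography → 3) and is meant
to be replaced wholesale by users with their own ratings. Unknown method
codes either raise or fall back to level 1, per configuration. The config
validator enforces levels exactly {1,2,3}, probabilities strictly inside
(0,1), and curated strictly above every level probability.

Example configuration:

```yaml
curated_sources: [drugbank, omim, cosmic, hprd]
curated_probability: 0.999
level_probabilities: {1: 0.8, 2: 0.95, 3: 0.99}
method_levels:
  "MI:0018": 1
  "MI:0096": 2
  "MI:0114": 3
unknown_method_policy: default_level_1
synonym_map: {}
```

## Combining redundant records

The default combiner is unweighted Stouffer voting: each probability maps
to a standard-normal quantile, the quantiles are summed, and the sum maps
back through the normal CDF. Properties the tests pin down: a single
record is a fixed point; p and 1−p cancel to 0.5; n concordant records
above 0.5 are strictly reinforcing in n. The geometric mean is kept as a
selectable alternative and documents why it was rejected as the default:
it is bounded by its largest input, so agreement can never raise
confidence. Curated and experimental records for the same triple are
combined uniformly; giving curated records precedence would be a
one-line change but is not the default.

Numerical choices: inputs are clamped to [ε, 1−ε], ε = 10⁻⁶ (the quantile
diverges at the endpoints; no probability the evidence model assigns is
affected). The combined value is nudged off exact 0/1 only (it must stay
usable inside joint-probability products). scipy's `ndtr`/`ndtri` provide
the CDF and quantile; the test suite checks the combiner against a
separately written erf + bisection oracle to 10⁻⁹.

Before combining, records identical in (source database, primary
reference, method, triple) are deduplicated (count logged). This is a
cheap mitigation of non-independence — the same physical experiment
syndicated by several aggregator databases would otherwise vote twice. It
is toggleable (`deduplicate=False`, CLI `--no-dedup`) to reproduce the
uncorrected behaviour; it does not attempt the harder problem of
detecting re-publications with distinct references.

## Path expansion

Joint probability of a path is the product of its edge probabilities
(empty product = 1). The search is a depth-first enumeration of simple
paths (no node revisits — cycles only lower the joint probability and a
revisit has no mechanistic meaning) bounded by `max_steps` and pruned the
moment a partial product drops below `min_joint_probability`; pruning is
lossless because the product is non-increasing under extension. The
endpoint type filter applies to the terminal node only; intermediate
nodes are unrestricted, so proteins may intervene between a drug and the
disease. Equivalence with an exhaustive enumerate-then-filter oracle is
asserted over 200 seeded random graphs.

Candidate discovery groups paths by terminal drug and keeps the best path
per drug: highest joint probability, then fewest steps, then
lexicographically smallest node sequence (a total order, so output is
deterministic). "Steps" counts edges on the drug→…→disease path. The
table sorts by joint probability descending, steps ascending, drug label,
and exports with probabilities at 6 decimal places and pipe-separated
path columns.

## Evaluation

Hits are every labelled status except `novel` (statuses: approved,
phase_iii, phase_ii, phase_i, case_study, in_vitro, in_vivo, novel).
Precision = hits returned / candidates returned; recall = hits returned /
all known hits; both 0 with a logged warning when a denominator is 0.
Unlabelled candidate pairs are errors in strict mode and non-hits
otherwise. The f-measure defaults to the harmonic mean; a geometric
variant is selectable (`--f-mean geometric`) because the balanced-mean
definition is genuinely ambiguous in this setting and the choice does not
move the benchmark's optimal threshold. Sweeps hold the other axis at its
default (steps ≤ 3 while sweeping probability, p ≥ 0.93 while sweeping
steps) and break f-measure ties toward the stricter threshold — higher
probability, fewer steps — which is how a 0.80–0.93 plateau still reports
0.93.

Scott's Pi uses pooled marginals: Ao is the fraction of items the two
annotators agree on, Ae = Σ q̂c² over the pooled category proportions, and
Pi = (Ao − Ae)/(1 − Ae); Ae = 1 (a single shared category) is an error,
not a 0/0.

## Synthetic data

The random generator plants a PPI backbone (Bernoulli edge density,
record multiplicity 1 + Poisson, evidence classes drawn from a configured
mix), drug→target fans (1–3 targets per drug) and gene–disease
associations (2–5 genes per disease), writing the three table dialects,
the evidence config and a manifest of every record's expected probability
so downstream edge probabilities are independently recomputable. All
randomness flows from one seeded `numpy` generator; identical seeds give
byte-identical files. Defaults (12 drugs, 30 proteins, 3 diseases,
density 0.08, mean multiplicity 1.6, mix 10% curated / 30% / 35% / 25%
levels 1–3) are desk-scale: large enough for non-trivial path structure,
small enough that property tests run in milliseconds.

The melanoma benchmark replays the published case-study neighbourhood: 25
candidate drugs with the published discovery statuses, step counts (2 or
3) and joint probabilities rounding to 0.93 / 0.95 / 0.97 / 0.98. The
published per-edge probabilities are not recoverable, so the benchmark
plants values that reproduce the printed roundings through the real
pipeline, using its own evidence config (curated 0.99; levels 0.8 / 0.95
/ 0.97): 2-step paths are two curated edges (0.99² = 0.9801 → 0.98);
3-step paths run drug → target(0.99) → PPI middle edge → disease
gene(0.99) with the middle edge a single level-2 record (→ 0.93), a
single level-3 record (→ 0.95), or three reinforcing level-1 records
(Φ(3Φ⁻¹(0.8)) ≈ 0.9942 → 0.97), the last exercising composite-Z voting
end to end. Decoys make the filter non-trivial: six implausible drugs
with weak 3-step paths (joint ≈ 0.784, labelled novel) that depress
precision below the operating point, and two drugs on strong 4-step
chains (joint ≈ 0.979, labelled phase II) that only appear when the step
allowance rises — together these make 0.93 / 3 steps the f-measure
optimum of the sweeps.

What the benchmark does and does not show: passing it demonstrates that
ingestion, scoring, combination, search and evaluation reproduce the
published filtering behaviour exactly on a network with known ground
truth. It does not validate the evidence model against real biology — the
real knowledge base had ~900k interactions, redundant records with
heterogeneous methods, and identifier noise that the synthetic tables do
not emulate.

## Limitations

* Only binary interactions are ingested; n-ary/complex rows are counted
  and skipped, so mechanisms through complexes are invisible.
* Biological-process (GO annotation) edges are not generated or ingested;
  the process entity type exists but no source dialect populates it.
* The probability model treats surviving records as independent;
  deduplication removes only exact provenance duplicates.
* Path search is exact enumeration with pruning — appropriate at desk
  scale and for threshold regimes near 1, but not tuned for dense graphs
  at permissive thresholds, where simple-path counts explode
  combinatorially.
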