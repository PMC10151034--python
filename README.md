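# rxgraph

Evidence-weighted biomedical knowledge graphs and joint-probability path
search for drug repositioning.

## The problem

Drug repositioning asks whether an existing drug might treat a disease it
was never developed for. Mechanistic evidence for such hypotheses is
scattered across databases of drug–target relations, protein–protein
interactions and gene–disease associations, each with very different
reliability: a manually curated drug–target entry is far more trustworthy
than a single yeast two-hybrid interaction. `rxgraph` integrates these
sources into one typed graph (drug / protein / gene / disease / process
nodes), attaches a probability to every assertion based on the quality of
its evidence, and searches the graph for high-confidence mechanistic chains
drug → target → disease gene → disease.

## The model

**Assertion probabilities.** Every interaction record carries provenance.
Manually curated assertions (drug–target, gene–disease) receive a fixed
probability *p* = 0.999. Experimentally derived assertions receive a
probability from the reliability level of the detection method, rated 1–3
by expert annotators: *p* = 0.8, 0.95 and 0.99 for levels 1, 2 and 3. The
method-code → level mapping is configuration, not code, and ships with an
illustrative default (two-hybrid → 1, pull-down → 2, X-ray
crystallography → 3).

**Edge combination.** All records asserting the same
(subject, interaction type, object) triple collapse into one edge. Its
probability combines the record probabilities by composite *Z*-score
voting (unweighted Stouffer combination):

    P(x₁…ₙ) = Φ( Σᵢ Φ⁻¹(P(xᵢ)) )

so independent concordant reports reinforce each other — two records at
0.8 combine to ≈ 0.954 — unlike the geometric mean (selectable as an
alternative), which can never exceed its largest input. Exact provenance
duplicates (the same experiment syndicated by several databases) are
dropped before combining, since they would otherwise inflate the vote.

**Path search.** The probability that a drug influences a disease through
a chain of interactions is the joint probability of the chain, the product
Π P(xᵢ) of its edge probabilities. Candidate discovery enumerates simple
paths from the disease over incoming links, pruning any partial path whose
joint probability falls below threshold (sound, because extending a path
never raises its probability), and reports each drug that terminates a
path, ranked by its best path. The default operating point — joint
probability ≥ 0.93 within ≤ 3 interaction steps — is where the
precision/recall trade-off of the melanoma case study peaks.

**Evaluation.** A candidate drug–disease pairing is a *hit* if it has
published in vivo / in vitro support or has been in a clinical trial.
Precision, recall and f-measure (harmonic mean by default, geometric
selectable) are computed against a status-labelled table, and threshold
sweeps over either axis locate the f-optimal cutoff. Scott's Pi quantifies
the agreement between the two method-reliability annotators.

## Worked example

The package ships a deterministic benchmark replica of the melanoma
case-study neighbourhood — 25 known candidate drugs with planted paths
whose joint probabilities round to the published values, plus decoys that
fail the published filter:

```
$ rxgraph fixtures melanoma --out data
$ rxgraph build --mitab data/ppi_mitab.tsv --drug-targets data/drug_targets.tsv \
    --omim data/gene_disease_omim.tsv --cosmic data/gene_disease_cosmic.tsv \
    --evidence-config data/evidence_config.yaml --out graph.jsonl
entities=70 edges=69 records=79 -> graph.jsonl
$ rxgraph candidates --graph graph.jsonl --disease melanoma --out candidates.csv
25 candidates -> candidates.csv
$ rxgraph evaluate --candidates candidates.csv --labels data/labels.tsv
precision=0.8800 recall=0.9167 f_measure=0.8980
$ rxgraph evaluate --labels data/labels.tsv --sweep-axis joint_probability \
    --graph graph.jsonl --disease melanoma
optimal joint_probability threshold: 0.93
```

`candidates.csv` lists each drug once with its best path, e.g.
Vemurafenib reaches melanoma in 2 steps through BRAF with joint
probability 0.980100 (0.99 drug–target × 0.99 gene–disease), and the
three-record reinforced CXCR4 edge puts Framycetin at 0.974428 ≈ 0.97 in
3 steps. Precision 0.88 means 22 of the 25 returned drugs are validated
hits; recall 0.9167 means those 22 cover all but two of the 24 known hits
(two planted decoy hits sit 4 steps out, beyond the step limit).

The same pipeline is available as library calls (`rxgraph.build_graph`,
`rxgraph.find_candidates`, `rxgraph.threshold_sweep`); synthetic random
networks with a ground-truth manifest come from
`rxgraph fixtures random --seed N --out DIR`.

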