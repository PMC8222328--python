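# pathreg

Identification of biological-pathway regulators from gene-expression
compendia.

Given an already-normalized expression matrix (microarray intensities, FPKM,
TMM-scaled counts, ...), the list of a pathway's structural genes and a list
of candidate transcription factors (TFs), `pathreg` ranks the TFs most likely
to regulate the pathway using two complementary engines, builds the inferred
TF → gene network, and scores rankings against known positive regulators.
It is aimed at computational biologists shortlisting regulator candidates
for experimental validation — for example, regulators of lignin or flavonoid
biosynthesis from stem or xylem compendia.

## The two engines

**TGMI (triple-gene mutual interaction).** Every (TF, pathway-gene-pair)
triple block (t, g_i, g_j) is scored on discretized expression with three
conditional mutual information statistics,

    I(t; g_i | g_j),   I(t; g_j | g_i),   I(g_i; g_j | t),

each with an exact permutation p-value, p = (1 + #{null ≥ obs}) / (R + 1).
A block is significant when both TF-involving statistics reject at level α;
significant blocks are collapsed into a bipartite network and TFs are ranked
by connectivity — the number of distinct pathway genes they are linked to.
The mean of the three CMIs (the mutual interaction measure, MIM) weights
edges and breaks ties. Being information-based, TGMI also detects nonlinear
regulation that correlation-based methods miss.

**SPLS (sparse partial least squares).** The pathway block Y (n × q) is
regressed on the TF block X (n × p, p ≫ n allowed) with soft-thresholded
PLS direction vectors, w = sign(u)(|u| − η·max|u|)₊ for u the dominant
singular vector of XᵀY. Sparsity η ∈ [0, 1) and component count
K ≤ min{p, (v−1)n/v} are chosen by v-fold cross-validated mean squared
prediction error. TFs are ranked by the number of responses with nonzero
coefficients.

`pathreg.evaluation` builds ROC curves against a positive-regulator list
(negatives = all other candidate TFs; sensitivity = TP/(TP+FN)·100,
specificity = TN/(TN+FP)·100) with trapezoidal AUROC, and
`pathreg.simulate` generates benchmark compendia with planted regulators,
TF multicollinearity, tight target co-expression and optional nonlinear
links. See `docs/methods.md` for the full model description and measured
limitations.

## Worked example

Simulate a benchmark compendium, run both engines, and compare them against
the planted truth:

```sh
pathreg simulate --preset easy --out-prefix sim
pathreg tgmi --expr sim.expr.tsv --pathway sim.pathway.txt --tf sim.tf.txt \
    --permutations 100 --seed 7 --out-prefix tgmi_run
pathreg spls --expr sim.expr.tsv --pathway sim.pathway.txt --tf sim.tf.txt \
    --seed 7 --out-prefix spls_run
python -c "import json; t=json.load(open('sim.truth.json')); \
    print('\n'.join(t['regulator_ids']))" > positives.txt
pathreg evaluate --ranking tgmi_run.ranking.tsv --ranking2 spls_run.ranking.tsv \
    --positives positives.txt --universe sim.tf.txt --top-k 50 --out report.json
```

The TGMI run prints (abridged):

```
Triple-gene mutual interaction (TGMI)
  TFs: 300  pathway genes: 20  samples: 200
  triplets scored: 57000  significant: 1272 (alpha=0.05, rule=both-tf, R=100)
  network edges: 1901

Top regulators by connectivity:
  rank  tf_id  connectivity  n_triplets  strength method
     1 TF0059            15          11    0.0681   tgmi
     2 TF0145            15          10    0.0774   tgmi
     ...
     6 TF0122            12          12    0.1194   tgmi
```

57,000 triple blocks were scored (300 TFs × C(20,2) gene pairs) and 1,272
were jointly significant. The first planted regulator (`TF0122`, which
drives three pathway genes with effect size 1) appears at rank 6; the
highest-connectivity entries are bystander TFs that chanced into
significance with a tightly co-expressed gene cluster — note their lower
mean interaction strength. The `evaluate` report gives each method's AUROC
against the eight planted regulators and how many land in each top-50: on
this preset SPLS attains AUROC 1.0 (its active set is exactly the planted
regulator set) while TGMI reaches ≈ 0.85 with 5/8 in its top-50
(connectivity saturates under tight co-expression; see `docs/methods.md`).
On the `nonlinear` preset the ordering flips decisively (TGMI ≈ 0.82,
SPLS ≈ 0.50, 0/8 in the top-50) — the complementarity the two engines ship
together for.

The same pipeline runs on real data by substituting your expression TSV
(genes × samples), pathway-gene list and TF list (one ID per line), plus a
literature-derived positives list for `evaluate`.

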