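# locnet

Protein multi-location prediction with a collection of Bayesian network
classifiers that model and exploit **inter-dependencies among subcellular
locations**.

## The problem

Many proteins localize to more than one subcellular compartment, and
compartments are not independent: proteins shuttle between designated
pairs of locations (cytoplasm/nucleus being the classic example), so
knowing that a protein is likely in one compartment changes the odds for
the others.  Most multi-location predictors score each location
independently, throwing that information away.

`locnet` trains one classifier per location that conditions on *estimates
of all the other locations* alongside the protein's features.  Each
protein is a numeric feature vector **f**ᴾ = (f₁ᴾ, …, f_dᴾ) with a binary
location-indicator vector **l**ᴾ = (l₁ᴾ, …, l_qᴾ) over q compartments.
For each location sᵢ a Bayesian network classifier Cᵢ = (Gᵢ, Θᵢ) is
learned over the discretized feature variables F₁…F_d and the location
variables L₁…L_q, with the joint factorizing as

    Pr(F₁…F_d, L₁…L_q) = ∏ᵢ Pr(Fᵢ | Pa(Fᵢ)) · ∏ⱼ Pr(Lⱼ | Pa(Lⱼ))

(no edges between feature nodes).  At prediction time, q one-vs-rest RBF
SVMs supply hard indicator estimates l̂₁ᴾ…l̂_qᴾ, and each classifier
outputs

    Cᵢ(P) = 1  iff  Pr(Lᵢ = 1 | fᴾ, l̂₁ᴾ…l̂ᵢ₋₁ᴾ, l̂ᵢ₊₁ᴾ…l̂_qᴾ) > 0.5.

The pipeline: recursive minimal-entropy (MDLP) discretization of each
feature → q SVM indicator estimators → per-location greedy hill-climbing
structure search maximizing a penalized conditional log likelihood (CLL)
of the target indicator → maximum-likelihood CPTs with pseudo-counts.
Evaluation uses the multi-label measures standard in this field:
example-based accuracy (Jaccard) and F1 (Dice), adapted per-location
multilabel precision/recall, their macro F1-label, and standard binary
precision/recall, under repeated stratified cross-validation.

## Worked example

No public corpus with precomputed feature tables ships with the package,
so the example uses the built-in synthetic corpus in which two
compartments (`mem`, `mi`) carry no feature signal at all and are
predictable only through their dependency on the other locations:

```python
from locnet import (TrainConfig, dependency_fixture_spec, sample_dataset,
                    train, predict, evaluate_predictions)

train_ds = sample_dataset(dependency_fixture_spec(n=2000, seed=0))
test_ds = sample_dataset(dependency_fixture_spec(n=500, seed=1))

model = train(train_ds, TrainConfig().with_seed(0))
for clf in model.classifiers:
    name = model.vocabulary.names[clf.target]
    print(name, [f"{clf.structure.node_name(u)}->{clf.structure.node_name(v)}"
                 for u, v in clf.structure.edges()])

report = evaluate_predictions(test_ds.Y, predict(model, test_ds),
                              model.vocabulary)
print(f"Acc = {report['acc']:.3f}, F1 = {report['f1']:.3f}, "
      f"F1-label = {report['f1_label']:.3f}")
```

prints

```
cyt ['F:f01->L:cyt']
ex ['F:f02->L:ex']
nuc ['F:f03->L:nuc']
mem ['F:f01->L:mem', 'L:ex->L:mem', 'L:nuc->L:mem']
mi ['F:f03->L:mi', 'L:ex->L:mi']
Acc = 0.949, F1 = 0.962, F1-label = 0.971
```

Each driver compartment's network found its one informative signature
feature, and the two feature-less compartments learned incoming edges
from the location nodes they depend on — the inter-location edges are
what makes them predictable at all.  The held-out example-based F1 of
0.96 compares with 0.87 for the same SVMs used alone (see below).

The same workflow is available from the shell:

```bash
locnet simulate --fixture dependency --n 2000 --seed 0 \
    --out-features feat.tsv --out-labels lab.tsv
locnet train --features feat.tsv --labels lab.tsv --seed 0 --out model.json
locnet predict --model model.json --features feat.tsv --out pred.tsv
locnet cv --features feat.tsv --labels lab.tsv --runs 5 --folds 5 --seed 0
```

Input formats are plain TSV/CSV: a features file (`id` column + numeric
columns) and a labels file (`id` + one 0/1 column per location, or a
single comma-separated `locations` column).

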