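# glycoshift

Machine-learning classification of pyranosyl di- and trisaccharides
from **unassigned** 13C NMR chemical shifts.

A proton-decoupled 13C spectrum of a small oligosaccharide is cheap to
record, but assigning its peaks to individual carbons is not. This
package asks how much structural information can be recovered *without
assignment*: the shift list is simply sorted ascending and padded into
a fixed 23-slot descriptor vector, and classifiers predict nine
structural properties per spectrum — the anomeric configurations of up
to three linkages, the two linkage types (1→2, 1→3, 1→4, 1→6), the
identities of the reducing-end, middle and terminal residues (Glc, Gal,
Man, Rha, Fuc), and whether a trisaccharide is linear or branched.
Properties that do not exist for a disaccharide are labelled `X` ("not
applicable") and treated as ordinary classes.

Three classifier families are implemented from scratch:

* **Random forest** (bagged CART with random descriptor subsets,
  out-of-bag error, permutation and Gini importances, proximities),
* **Classification trees** (CART with Gini impurity and
  cross-validated cost-complexity pruning, plus a fixed published rule
  cascade for the reducing-end anomeric configuration),
* **Counterpropagation neural networks** (a toroidal Kohonen map with a
  per-task look-up output layer), with the map also used for a
  diversity-based train/test split.

Because assigned experimental spectra cannot be redistributed, the
benchmark data are simulated by an additive increment model that
reproduces the coarse layout of pyranose 13C spectra; see
[docs/methods.md](docs/methods.md) for exactly what the generator does
and does not emulate.

## Worked example

```python
from glycoshift.simulate import default_increment_model, generate_dataset
from glycoshift.encoding import descriptor_matrix
from glycoshift.records import labels_frame, TASKS
from glycoshift.som import diversity_split
from glycoshift.trees import train_rf, oob_report
from glycoshift.evaluation import ConfusionMatrix, mean_predictability

# 273 simulated spectra: 154 disaccharides + 119 trisaccharides
model = default_increment_model(noise_sd=0.3)
ds = generate_dataset(273, {"n_di": 154, "n_tri": 119}, model, seed=7)

# Kohonen-map based diversity split, 69 test compounds
train_ids, test_ids = diversity_split(ds.records, n_test=69, seed=7)
by_id = {r.id: r for r in ds.records}
train = [by_id[i] for i in train_ids]
test = [by_id[i] for i in test_ids]

X_tr, _ = descriptor_matrix(train)
X_te, _ = descriptor_matrix(test)
y_tr = list(labels_frame(train).reset_index(drop=True)["ano_r"])
y_te = list(labels_frame(test).reset_index(drop=True)["ano_r"])

# reducing-end anomeric configuration (alpha = A, beta = B)
forest = train_rf(X_tr, y_tr, n_trees=500, seed=7,
                  classes=TASKS["ano_r"], task="ano_r")
report, _ = oob_report(forest, X_tr, y_tr)
print(f"OOB mean predictability (ano_r): {report.mean_predictability:.2f}")

pred = forest.predict(X_te)
cm = ConfusionMatrix.from_labels("ano_r", TASKS["ano_r"], y_te, list(pred))
print(f"test mean predictability (ano_r): {mean_predictability(cm):.2f}")
print(cm.counts)
```

Output:

```
OOB mean predictability (ano_r): 95.51
test mean predictability (ano_r): 90.20
[[33  5]
 [ 2 29]]
```

(`diversity_split` warns that only 33 singly occupied map neurons exist
for 69 requested test compounds and falls back to least-occupied
neurons; that is expected at this split size.)

The same workflow is available from the command line:

```sh
glycoshift simulate --n 273 --di 154 --tri 119 --seed 7 --out data.tsv
glycoshift split --in data.tsv --test-count 69 --seed 7 \
    --out-train train.tsv --out-test test.tsv
glycoshift train --method rf --task ano_r --in train.tsv \
    --model rf.json --seed 7 --n-trees 500
glycoshift evaluate --model rf.json --in test.tsv --out eval.tsv
```

or as a single configured pipeline run (`glycoshift run --config
config.yaml --out-dir out/`), which writes the dataset, split, per-task
reports for every requested method, and a comparison table; reruns with
the same configuration are byte-identical apart from the timing log.

## Reproduction

All randomness is seed-controlled. To regenerate the headline summary
quantities (per-task mean predictability for the forest's out-of-bag
estimate and the 10-fold cross-validated network and tree, on the
default 273-record benchmark):

```sh
python scripts/acceptance.py --seed 7 --out results.json
```

The test suite pins the numerical behaviour, including published
per-class count tables, oracle checks of the split and winner searches,
permutation-null chance levels, and pipeline determinism:

```sh
python -m pytest -q tests/
```

See [docs/methods.md](docs/methods.md) for model details, reporting
conventions (mean predictability is the unweighted mean of per-class
sensitivities; "specificity" follows the precision convention), and
limitations.
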