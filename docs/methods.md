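# Methods

This document describes the models implemented in `glycoshift`, the
simulated benchmark data, the numerical conventions, and the known
limitations. Everything stated here is either a design decision of this
package or a quantity the package itself computes.

## Problem setting

The input to every classifier is a single unassigned proton-decoupled
13C spectrum of a pyranosyl di- or trisaccharide, reduced to its list of
chemical shifts. Because the shifts are unassigned, the list is sorted
ascending and right-aligned into a fixed 23-slot descriptor vector
(`C1`…`C23`): a disaccharide with 12 carbons fills `C12`…`C23` and the
leading slots are zero. `C23` is therefore always the largest shift in
the spectrum — for N-acetylated residues it is the carbonyl resonance.
The encoding is permutation-invariant by construction: any ordering of
the same shifts produces the same descriptor vector.

Nine classification tasks are defined per spectrum, each over a small
class alphabet:

| task | meaning | classes |
|---|---|---|
| `ano_f` | anomeric configuration, first (reducing-end) linkage | α (`A`), β (`B`) |
| `ano_s` | anomeric configuration, second linkage | `A`, `B`, `X` |
| `ano_r` | anomeric configuration of the reducing residue | `A`, `B` |
| `f_link` | first linkage type | 1→2 (`A`), 1→3 (`B`), 1→4 (`C`), 1→6 (`D`), `X` |
| `s_link` | second linkage type | `A`–`D` |
| `red_end` | reducing-end residue | Glc (`A`), Gal (`B`), Man (`C`), Rha (`D`), Fuc (`E`) |
| `m_residue` | middle residue | `A`–`E`, `X` |
| `f_residue` | first (non-reducing) residue | `A`–`E` |
| `chain_type` | chain topology of trisaccharides | linear (`A`), branched (`B`), `X` |

`X` means "not applicable"; for disaccharides exactly `ano_s`,
`f_link`, `m_residue` and `chain_type` are `X`.

## Simulated spectra

Real spectra are not shipped. The generator (`glycoshift.simulate`)
produces spectra from an additive increment model:

* Each residue type carries a base monosaccharide shift table; ring
  carbons involved in a glycosidic bond receive fixed glycosylation
  increments (downfield for the linkage carbon, smaller shifts for its
  neighbours).
* Anomeric carbons are placed in stylised, configuration-dependent
  windows; within a window, positions are laid out on a small grid with
  a 1.3 ppm step indexed by configuration and residue rank, so that
  distinct (configuration, residue) combinations remain resolvable at
  low noise.
* N-acetyl groups contribute methyl and carbonyl resonances (the
  carbonyl at 175.3 ppm is the diagnostic maximum used by the published
  rule cascade); O-methyl groups contribute a methoxy resonance.
* Gaussian noise with configurable standard deviation (default
  0.3 ppm) is added to every shift, then shifts are clamped to the open
  interval (0, 230) ppm so extreme noise cannot produce physically
  impossible values.

What the generator emulates: the coarse layout of 13C shifts of
pyranoses (anomeric 90–110 ppm, ring 60–90 ppm, deoxy methyl <20 ppm,
carbonyl >170 ppm), glycosylation shifts, and the class-discriminating
structure that makes the nine tasks learnable but not trivial.

What it does **not** emulate: conformational and solvent effects,
second-order coupling, pH and temperature dependence, signal overlap or
missing peaks, and the true covariance between shifts of neighbouring
carbons. Absolute shift values are stylised and should not be compared
to measured spectra.

The default benchmark is 273 records (154 disaccharides, 119
trisaccharides) at 0.3 ppm noise, generated with seed 7. Composition
quotas per class can be requested explicitly; unsatisfiable quotas
raise an error rather than silently degrading.

## Self-organizing (Kohonen) map

`glycoshift.som` implements a rectangular toroidal map. Training uses
competitive learning with a Gaussian neighbourhood kernel on the
toroidal grid distance, a learning rate decaying linearly from 0.5 to
0.01, and a neighbourhood radius decaying linearly from max(height,
width)/2 to 0 over the epochs. The winning neuron is the one with the
smallest Euclidean distance to the input; exact ties resolve to the
smallest (row, column) pair.

Map sizing follows the rule `side = ceil(sqrt(factor · n))` with
default factor 1.3, so 92 training objects give an 11×11 map
(121 neurons) and 119 give 13×13.

The map also drives the diversity-based train/test split: objects are
mapped, and the test set is drawn across occupied neurons so that it
spans the data's self-organized clusters. A warning is emitted when
singly occupied neurons force near-unique objects into one side of the
split.

## Counterpropagation network

`glycoshift.cpgnn` stacks an output (Grossberg) layer per task on top
of the Kohonen layer. During training, the output block of the winning
neuron (and its neighbours, weighted by the same Gaussian kernel) moves
toward the one-hot encoding of the object's class; the schedule mirrors
the map schedule. Prediction looks up the winning neuron for an input
and returns the class with the largest output weight; exact ties
resolve to the first class in the task alphabet. Ten-fold
cross-validation is stratified on `chain_type` (with a plain shuffled
fallback when stratification is infeasible) and refuses datasets with
fewer than ten objects, suggesting leave-one-out instead.

## Classification trees and random forest

`glycoshift.trees` implements CART with Gini impurity. Splits are
binary, axis-aligned, at midpoints between consecutive observed values;
the left branch takes values strictly below the threshold. Among
equally good splits the lowest descriptor index, then the lowest
threshold, wins. Growing stops at pure nodes, at fewer than `min_split`
objects, or when no split decreases impurity. Pruning is
cost-complexity: the pruning path is computed, candidate subtrees are
evaluated by 10-fold cross-validation at representative α values
(midpoints between consecutive knots), and among candidates within the
minimum the simplest tree is kept.

The random forest draws bootstrap samples, restricts each split to
`mtry` (default 4) randomly chosen descriptors, and aggregates by
majority vote. Out-of-bag (OOB) estimates use, for each object, only
the trees that did not see it; a warning is raised when every tree saw
every object (e.g. a single-tree forest). Variable importance is
reported both as mean decrease in accuracy (per-tree OOB permutation of
one descriptor) and mean decrease in Gini; proximities count how often
two objects share a leaf.

A fixed published rule cascade for the reducing-end anomeric
configuration is available as `apply_reference_tree`; its thresholds
(72.52, 57.16, 96.52, 175.3 ppm on descriptors `C16`, `C6`, `C21`,
`C23`) are hard-coded and not refitted.

## Reporting conventions

Per class, *sensitivity* is correct/size over the true class and
*specificity* follows the precision convention: correct predictions of
a class divided by all predictions of that class (the standard
true-negative-rate is also available as `specificity_standard`). The
headline figure, *mean predictability*, is 100 × the unweighted mean of
class sensitivities over non-empty classes; `X` counts as an ordinary
class. Undefined metrics (empty classes) render as `---` in tables.

## Determinism

All stochastic components (simulation, bootstrap, map initialisation
and presentation order, fold shuffling, permutation importance) are
driven by explicit integer seeds through `numpy.random.default_rng`.
The pipeline writes byte-identical artifacts across reruns with the
same configuration, except for the timing log.

## Limitations

* All performance figures in this repository are measured on simulated
  spectra; they characterise the methods under the generator's
  assumptions, not accuracy on measured spectra.
* The descriptor encoding discards multiplicities and intensities and
  cannot represent accidental peak overlap.
* Tasks with many classes and few objects per class (notably the
  reducing-end residue) are hard for the winner-take-all network
  look-up, which fragments small classes across map neurons; the forest
  is consistently the stronger model on the default benchmark.
* The CART cross-validated pruning can select different tree sizes for
  nearby seeds when the α path has near-tied candidates; this is
  inherent to the procedure, not an instability of the implementation.
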