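# dtirank

Neural learning-to-rank models for drug–target interaction (DTI)
prediction, with similarity-regularized matrix-factorization baselines
and the cross-validation protocols used to evaluate them.

## The problem

Experimentally verified drug–target interactions are scarce: a binary
matrix **Y** ∈ {0,1}<sup>n×m</sup> over *n* compounds and *m* proteins is
mostly zeros, and a zero means *unobserved*, not *non-interacting*.  The
practical question is ranking: for each drug, which unverified targets
are most likely to interact?  Side information helps — chemically similar
compounds tend to hit similar proteins — so drug–drug similarities
(e.g. SIMCOMP common-substructure scores) and target–target similarities
(normalized Smith–Waterman) enter as regularizers.

## The models

All three neural variants share one architecture: embedding lookups
**p**<sub>d</sub> = **P**ᵀ**E**<sub>d</sub>,
**q**<sub>t</sub> = **Q**ᵀ**E**<sub>t</sub>, an element-wise-product
interaction layer **h**₀ = **p**<sub>d</sub> ⊙ **q**<sub>t</sub>, a ReLU
multilayer perceptron, and a linear head producing a raw score
x<sub>dt</sub>.  They differ in the loss:

* **point-wise** — squared error Σ (y<sub>dt</sub> − σ(x<sub>dt</sub>))²
  over observed positives and sampled negatives;
* **pair-wise** — Bayesian-personalized-ranking loss
  −Σ ln σ(x<sub>dt</sub> − x<sub>di</sub>) over triples with t verified
  and i unobserved for drug d;
* **list-wise** — cross entropy against the top-one (softmax)
  probability of lists holding one positive and K sampled negatives.

Each objective can add the similarity penalty
λ<sub>d</sub>‖**S**<sup>d</sup> − **PP**ᵀ‖²<sub>F</sub> +
λ<sub>t</sub>‖**S**<sup>t</sup> − **QQ**ᵀ‖²<sub>F</sub>, which ties the
embedding Gram matrices to the precomputed similarities and is what
carries signal to *cold-start* drugs with no training interactions.
Baselines PMF, CMF (MF with the same similarity penalty), and BPR-MF
score by the plain inner product.  Everything is optimized with Adam;
gradients are hand-written numpy backpropagation, verified against
finite differences in the test suite.

Evaluation follows two 10-fold protocols: **CV_dt** holds out random
drug–target cells, **CV_nd** holds out whole drug rows (new drugs), with
per-fold AUC and AUPR.

## Worked example

Generate a planted dataset (latent rank-8 factors drive both the
interactions and the similarity matrices), then cross-validate the
list-wise model:

```bash
dtirank simulate --n 100 --m 80 --k-true 8 --density 0.08 \
    --sim-noise 0.05 --seed 1 --out sim/
dtirank cv --interactions sim/interactions.tsv \
    --drug-sim sim/drug_sim.tsv --target-sim sim/target_sim.tsv \
    --model listwise --setting cv_dt --k 32 --tau 0.005 \
    --lam-d 0.01 --lam-t 0.01 --epochs 200 --seed 1 --out cv_out/
```

which prints

```
listwise cv_dt: AUC 0.9455 +/- 0.0121, AUPR 0.6867 +/- 0.0458
```

AUC is the probability that a held-out verified pair outscores a
held-out unobserved pair (1.0 = perfect ranking, 0.5 = chance); AUPR is
the area under the precision–recall curve, the stricter metric under the
92% class imbalance here.  Per-fold values land in `cv_out/eval.tsv` and
the fully resolved configuration in `cv_out/manifest.json`.  The same
interface accepts the tab-separated "admat"/"simmat" files of the public
gold-standard DTI datasets (`--orientation auto` recognizes their
targets-as-rows layout by the `hsa` protein prefix).

Other subcommands: `train` (fit one model, save a reloadable archive),
`predict` (rank unobserved targets per drug), `gridsearch` (exhaustive
hyperparameter search by validation AUC).

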