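# gosel

Multi-label protein function prediction with automatic selection of the
informative feature matrices from multi-channel protein–protein
interaction (PPI) networks.

STRING-style resources give seven PPI networks per organism — one per
evidence channel (neighborhood, fusion, cooccurence, coexpression,
experimental, database, textmining) — plus protein attributes such as Pfam
domains and subcellular locations. Which of these actually help predict
Gene Ontology (GO) terms differs by organism and GO aspect, and simply
concatenating everything dilutes the signal. `gosel` trains two networks
together:

- a **Classifier**: one ReLU projection per feature matrix, whose selected
  branch outputs are averaged and scored by a two-layer head, trained with
  the asymmetric loss `ASL = (1/NK) Σ [ −y (1−p)^{γ+} log p −
  (1−y) p^{γ−} log(1−p) ]` (γ+ = 0, γ− = 2), and
- a **Selector**: a small surrogate MLP that maps a binary mask over the
  matrix space to a predicted validation loss; the absolute gradient of its
  output with respect to an all-0.5 probe mask ranks the matrices.

Training alternates exploration (random masks), gradient-guided
exploitation (candidate subsets of the top-ranked matrices), and a final
refinement under the best recorded mask `m*`, reporting CAFA-style metrics
(Fmax, micro-/macro-AUPR, F1, macro-F1, subset accuracy) on a temporal
holdout. A planted-signal synthetic generator makes the whole pipeline
testable without downloads. See `docs/methods.md` for the model and all
numerical choices.

Intended users: computational biologists benchmarking network-based
function prediction, and method developers who need a tested, desk-scale
reference implementation of surrogate-guided feature-matrix selection.

## Worked example

```python
import numpy as np
from gosel import DualNetworkClassifier, SyntheticSpec, generate_planted_dataset

# 600 proteins, 8 candidate matrices, only #1 and #6 carry label signal
space, labels, planted = generate_planted_dataset(SyntheticSpec(seed=3))

est = DualNetworkClassifier(random_state=3)   # N_f=2, E1=100, E2+E3=100
est.fit(space, labels)

print("planted:", planted)
print("selected:", tuple(int(i) for i in np.flatnonzero(est.mask_)))
print("test Fmax:", round(est.eval_result_.fmax, 3),
      "micro-AUPR:", round(est.eval_result_.m_aupr, 3))
```

Output:

```
planted: (1, 6)
selected: (1, 6)
test Fmax: 0.745 micro-AUPR: 0.784
```

The selector found exactly the two matrices the generator planted, and the
classifier trained on them reaches test Fmax 0.745 — against roughly 0.6
when all eight matrices are forced on (the six noise matrices dilute the
branch average) and about 0.3 for the naive frequency baseline.

The same pipeline runs from files:

```bash
gosel synth --out data/ --seed 7                 # edge lists, annotations, attributes
gosel embed --data data/ --backend transformerae --out cache.h5
gosel train --data data/ --cache cache.h5 --aspect BP --nf 2 \
            --max-label-frac 1.0 --seed 7 --out run/
gosel baseline naive --data data/ --max-label-frac 1.0
```

`gosel train` writes `report.json` (metrics + selected sources),
`record.jsonl` (every mask/loss evaluation), a checkpoint and the resolved
config, so a run directory replays exactly.

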