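"""Train the two-stage classifier and label unseen cells.

Stage 1: PLS-DA (3 latent components) separates lysed ghosts from intact
cells.  Stage 2: SIMCA models each of the four target morphologies with its
own PCA; cells accepted by no class fall into the "deformed" rejection
category.
"""

import numpy as np

from morphoscreen.classify import label_cells, train_classifiers
from morphoscreen.training import labeled_cell_features

counts = {"normal": 120, "small": 80, "elongated": 80, "round": 80, "deformed": 80, "lysed": 200}
X, labels = labeled_cell_features(counts, rng=0)
rng = np.random.default_rng(1)
idx = rng.permutation(len(X))
n_tr = int(0.7 * len(X))
train, test = idx[:n_tr], idx[n_tr:]

clf = train_classifiers(X[train], labels[train])
pred = label_cells(clf, X[test])

agree = (pred == labels[test]).mean()
print(f"trained on {n_tr} cells, tested on {len(test)}: agreement {agree:.1%}")
lysed_true = labels[test] == "lysed"
lysed_pred = pred == "lysed"
print(f"lysed-vs-intact: sensitivity {lysed_pred[lysed_true].mean():.1%}, "
      f"specificity {(~lysed_pred[~lysed_true]).mean():.1%}")
print("predicted label mix:", {c: int((pred == c).sum()) for c in sorted(set(pred))})
# Sensitivity/specificity quantify the lysed/intact gate; disagreements among
# intact cells concentrate in adjacent size classes (small vs normal).
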