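"""Class rebalancing by synthetic minority oversampling (SMOTE).

Every minority class is brought up to the size of the largest class by
interpolating new rows between a real minority row and one of its k nearest
same-class neighbors: ``x_new = x + u * (x_nn - x)`` with ``u ~ U(0, 1)``.
Distances are Euclidean on the native feature scale — no standardization is
applied before the neighbor search, matching a pipeline that deliberately
avoids intensity normalization.

Where rebalancing sits relative to cross-validation matters: applying SMOTE
before splitting leaks interpolated copies of test-set neighbors into
training folds.  :func:`wmtex.evaluation.run_nested_cv` therefore defaults
to balancing inside each outer training partition only, with a ``pre-split``
compatibility mode available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = ["CohortTable", "smote_balance"]


@dataclass
class CohortTable:
    """Subjects x features matrix with class labels and row provenance.

    ``features`` rows, ``labels`` and ``provenance`` share one index of
    subject ids; provenance marks each row ``real`` or ``synthetic_smote``.
    """

    features: pd.DataFrame
    labels: pd.Series
    provenance: pd.Series

    def __post_init__(self) -> None:
        if not (self.features.index.equals(self.labels.index)
                and self.features.index.equals(self.provenance.index)):
            raise ValueError("features, labels and provenance must share one index")
        if self.features.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        y: Sequence[str],
        feature_names: Optional[Sequence[str]] = None,
        ids: Optional[Sequence[str]] = None,
    ) -> "CohortTable":
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(X.shape[1])]
        if ids is None:
            ids = [f"s{i}" for i in range(X.shape[0])]
        idx = pd.Index(ids)
        return cls(
            features=pd.DataFrame(X, index=idx, columns=list(feature_names)),
            labels=pd.Series(list(y), index=idx, name="label"),
            provenance=pd.Series("real", index=idx, name="provenance"),
        )

    @property
    def n_subjects(self) -> int:
        return len(self.features)

    @property
    def classes(self):
        return tuple(sorted(self.labels.unique()))

    def class_counts(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def X(self, columns: Optional[Sequence[str]] = None) -> np.ndarray:
        df = self.features if columns is None else self.features[list(columns)]
        return df.to_numpy(dtype=float)

    def subset(self, positions: Sequence[int]) -> "CohortTable":
        positions = np.asarray(positions)
        return CohortTable(
            features=self.features.iloc[positions],
            labels=self.labels.iloc[positions],
            provenance=self.provenance.iloc[positions],
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.features.copy()
        df.insert(0, "label", self.labels)
        df["provenance"] = self.provenance
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortTable":
        if "label" not in df.columns:
            raise ValueError("cohort frame must have a 'label' column")
        prov = df["provenance"] if "provenance" in df.columns else pd.Series(
            "real", index=df.index, name="provenance"
        )
        feats = df.drop(columns=[c for c in ("label", "provenance") if c in df.columns])
        return cls(features=feats, labels=df["label"].rename("label"),
                   provenance=prov.rename("provenance"))


def smote_balance(table: CohortTable, k: int = 5, seed: Optional[int] = None) -> CohortTable:
    """Oversample every minority class up to the majority-class count.

    Original rows are preserved verbatim; each synthetic row lies on the
    segment between a minority row and one of its ``k`` nearest same-class
    neighbors.  ``k`` is truncated (with a warning) when a class is smaller
    than ``k + 1``; classes with fewer than two members cannot be
    interpolated and raise.  Output is deterministic for a fixed ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = table.class_counts()
    majority = int(counts.max())
    if (counts == majority).all():
        return CohortTable(
            features=table.features.copy(),
            labels=table.labels.copy(),
            provenance=table.provenance.copy(),
        )
    rng = np.random.default_rng(seed)
    new_rows, new_labels, new_ids = [], [], []
    for cls in table.classes:
        n = int(counts[cls])
        n_new = majority - n
        if n_new == 0:
            continue
        if n < 2:
            raise ValueError(
                f"class {cls!r} has {n} member(s); SMOTE needs at least 2"
            )
        k_eff = min(k, n - 1)
        if k_eff < k:
            warnings.warn(
                f"class {cls!r} has only {n} members; truncating k from {k} to {k_eff}",
                stacklevel=2,
            )
        Xc = table.features[table.labels == cls].to_numpy(dtype=float)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc)
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(0, n, size=n_new)
        pick = rng.integers(0, k_eff, size=n_new)
        u = rng.random(n_new)
        x = Xc[base]
        x_nn = Xc[neigh[base, pick]]
        new_rows.append(x + u[:, None] * (x_nn - x))
        new_labels.extend([cls] * n_new)
        new_ids.extend(f"{cls}_smote_{i}" for i in range(n_new))

    synth = pd.DataFrame(
        np.vstack(new_rows), index=pd.Index(new_ids), columns=table.features.columns
    )
    features = pd.concat([table.features, synth])
    labels = pd.concat([table.labels, pd.Series(new_labels, index=synth.index, name="label")])
    prov = pd.concat(
        [table.provenance,
         pd.Series("synthetic_smote", index=synth.index, name="provenance")]
    )
    return CohortTable(features=features, labels=labels, provenance=prov)
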