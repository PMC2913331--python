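"""Random-forest binary classifier layer.

A thin, swappable contract over a stock random-forest implementation,
pinned to the published configuration for the developmental-toxicity
endpoint: 10 trees with maximum depth 12, seeded for reproducibility.
Follows the same Model/fit/Results shape as the AFP layer.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier


class RFError(ValueError):
    pass


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 10
    max_depth: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise RFError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise RFError("max_depth must be >= 1")


class RandomForest:
    """Random-forest model specification bound to training data."""

    def __init__(
        self,
        X: pd.DataFrame,
        y: Sequence[str],
        config: RFConfig | None = None,
    ):
        if len(X) == 0:
            raise RFError("empty training matrix")
        if len(X) != len(y):
            raise RFError("X and y length mismatch")
        if X.isna().any().any():
            raise RFError("training matrix contains undefined descriptor cells")
        if len(set(y)) < 2:
            raise RFError("training labels contain a single class")
        self.X = X
        self.y = np.asarray(list(y), dtype=object)
        self.config = config or RFConfig()

    def fit(self) -> "RFResults":
        cfg = self.config
        forest = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            max_depth=cfg.max_depth,
            random_state=cfg.seed,
        )
        forest.fit(self.X.to_numpy(dtype=float), self.y)
        return RFResults(forest=forest, columns=list(self.X.columns), config=cfg)


class RFResults:
    """A fitted random forest with its configuration and column contract."""

    def __init__(
        self, forest: RandomForestClassifier, columns: list[str], config: RFConfig
    ):
        self.forest = forest
        self.columns = columns
        self.config = config
        self.classes = tuple(forest.classes_)

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.columns:
            raise RFError(
                f"column mismatch: expected {self.columns}, got {list(X.columns)}"
            )
        return X.to_numpy(dtype=float)

    def predict_classes(self, X: pd.DataFrame) -> list[str]:
        return list(self.forest.predict(self._check(X)))

    def vote_fractions(self, X: pd.DataFrame) -> np.ndarray:
        """Fraction of trees voting for the positive (last) class."""
        proba = self.forest.predict_proba(self._check(X))
        return proba[:, -1]

    def summary(self) -> str:
        return (
            "Random forest results\n"
            "=====================\n"
            f"trees:       {self.config.n_trees}\n"
            f"max depth:   {self.config.max_depth}\n"
            f"seed:        {self.config.seed}\n"
            f"classes:     {', '.join(map(str, self.classes))}\n"
            f"descriptors: {', '.join(self.columns)}"
        )

    def save(self, path) -> None:
        """Persist the fitted forest plus a JSON sidecar of the contract."""
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self.forest, fh)
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "format": "devtox-rf",
                    "version": 1,
                    "columns": self.columns,
                    "config": {
                        "n_trees": self.config.n_trees,
                        "max_depth": self.config.max_depth,
                        "seed": self.config.seed,
                    },
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, path) -> "RFResults":
        path = Path(path)
        with open(path, "rb") as fh:
            forest = pickle.load(fh)
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            doc = json.load(fh)
        if doc.get("format") != "devtox-rf":
            raise RFError("not a random-forest model sidecar")
        return cls(forest=forest, columns=doc["columns"], config=RFConfig(**doc["config"]))
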