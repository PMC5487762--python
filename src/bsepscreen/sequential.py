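"""Sequential (cascade) and consensus combination of classifiers.

A screening cascade applies a fast ligand-based classifier first and sends
only its positives to the structure-based model; a compound is a final
positive only when both stages agree. False positives and true positives
can therefore only shrink relative to the first stage, which is exactly the
mechanism that raises precision in large-scale toxicity screening.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .labels import UNPREDICTED, as_binary, from_binary

logger = logging.getLogger(__name__)

__all__ = ["cascade", "consensus", "cascade_report", "PredictionTable"]


def cascade(first, second) -> np.ndarray:
    """Two-stage cascade: inhibitor iff both stages say inhibitor.

    Compounds negative in the first stage are final negatives without
    consulting the second stage; an unpredicted first stage propagates, as
    does an unpredicted second stage for first-stage positives.
    """
    f = as_binary(first, allow_unpredicted=True)
    s = as_binary(second, allow_unpredicted=True)
    if f.shape != s.shape:
        raise ValueError("prediction vectors must cover the same compounds")
    out = np.where(f == 0.0, 0.0, np.where(np.isnan(f), np.nan, s * f))
    return from_binary(out, template=np.asarray(first, dtype=object))


def consensus(predictions: Sequence, rule: str = "majority") -> np.ndarray:
    """Majority vote over >= 2 aligned prediction vectors.

    Ties (possible with an even model count) go to non-inhibitor — the
    conservative call in a toxicity screen. Unpredicted entries do not vote;
    a compound with no votes at all is unpredicted.
    """
    if rule != "majority":
        raise ValueError(f"unknown consensus rule {rule!r}")
    if len(predictions) < 2:
        raise ValueError("consensus needs at least two models")
    mat = np.vstack([as_binary(p, allow_unpredicted=True) for p in predictions])
    votes_for = np.nansum(mat == 1.0, axis=0)
    votes_cast = (~np.isnan(mat)).sum(axis=0)
    out = np.where(votes_cast == 0, np.nan,
                   (votes_for > votes_cast / 2.0).astype(float))
    return from_binary(out, template=np.asarray(predictions[0], dtype=object))


class PredictionTable:
    """Aligned per-model predictions plus true labels for a compound panel."""

    def __init__(self, predictions: pd.DataFrame, truth: Sequence):
        self.predictions = predictions.copy()
        truth = pd.Series(list(truth), index=predictions.index, dtype=object)
        self.truth = truth

    @classmethod
    def from_long(cls, frame: pd.DataFrame, truth: Mapping[str, str]) -> "PredictionTable":
        """Build from long format (compound_id, model_name, predicted_label)."""
        wide = frame.pivot(index="compound_id", columns="model_name",
                           values="predicted_label")
        wide = wide.fillna(UNPREDICTED)
        return cls(wide, [truth[c] for c in wide.index])

    def add_cascade(self, first: str, second: str, name: str | None = None) -> str:
        name = name or f"{first} + {second}"
        self.predictions[name] = cascade(self.predictions[first], self.predictions[second])
        return name

    def add_consensus(self, models: Sequence[str], name: str = "Consensus") -> str:
        self.predictions[name] = consensus([self.predictions[m] for m in models])
        return name

    def report(self) -> pd.DataFrame:
        return cascade_report(self.predictions, self.truth)


def cascade_report(predictions: pd.DataFrame, truth: Sequence) -> pd.DataFrame:
    """Metrics table with one row per model column.

    Unpredicted compounds are excluded from that model's counts (their
    number is reported in ``n_unpredicted``).
    """
    rows = []
    truth = list(truth)
    for model in predictions.columns:
        pred = predictions[model].tolist()
        cm = _metrics.confusion(pred, truth)
        row = _metrics.classification_report_row(cm, model=model)
        row["n_unpredicted"] = len(pred) - cm.total
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
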