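"""Docking-score threshold classifiers.

The central model is the intersection-point classifier: the per-class score
distributions of inhibitors and non-inhibitors are binned, each class's bin
counts are normalized to relative frequencies (so a majority class cannot
dominate the crossing), and the score at which the two frequency polylines
cross becomes the decision threshold. For two equal-variance Gaussian
classes this converges to the equal-prior Bayes boundary, the midpoint of
the class means.

Also here: per-bin inhibitor probabilities with a chi-square enrichment test,
the MW/logP OR-rule, single-property threshold fitting, and the combined
model that averages a min-max-normalized docking score with normalized MW
and logP.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .labels import (
    HIGHER_IS_INHIBITOR,
    INHIBITOR,
    LOWER_IS_INHIBITOR,
    NON_INHIBITOR,
    ORIENTATIONS,
    as_binary,
    from_binary,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreTable",
    "BinnedDistribution",
    "ThresholdClassifier",
    "NoIntersectionError",
    "DegenerateFeatureError",
    "aggregate_poses",
    "bin_scores",
    "find_intersection",
    "classify_by_threshold",
    "bin_probability_table",
    "physchem_rule",
    "fit_property_threshold",
    "combined_score",
    "IntersectionClassifier",
    "PhyschemRuleClassifier",
    "CombinedScoreClassifier",
]

#: Default score orientations for the scoring functions consumed as inputs.
DEFAULT_ORIENTATIONS = {
    "ChemScore": HIGHER_IS_INHIBITOR,
    "GoldScore": HIGHER_IS_INHIBITOR,
    "XScore": HIGHER_IS_INHIBITOR,
    "GlideXP": LOWER_IS_INHIBITOR,
}


class NoIntersectionError(ValueError):
    """The class frequency curves never cross; carries both curves."""

    def __init__(self, message: str, centers=None, freq_inhibitor=None, freq_non_inhibitor=None):
        super().__init__(message)
        self.centers = centers
        self.freq_inhibitor = freq_inhibitor
        self.freq_non_inhibitor = freq_non_inhibitor


class DegenerateFeatureError(ValueError):
    """A normalization range has zero width."""


class ScoreTable:
    """Per-compound docking scores per scoring function, with orientations.

    Backed by a long-format DataFrame with columns ``compound_id``,
    ``scoring_function``, ``score``. Every scoring function present must have
    a declared orientation.
    """

    COLUMNS = ("compound_id", "scoring_function", "score")

    def __init__(self, frame: pd.DataFrame, orientations: Mapping[str, str] | None = None):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"score table missing columns {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)
        self.orientations = dict(DEFAULT_ORIENTATIONS if orientations is None else orientations)
        for fn in self.functions:
            if fn not in self.orientations:
                raise ValueError(f"no orientation declared for scoring function {fn!r}")
            if self.orientations[fn] not in ORIENTATIONS:
                raise ValueError(f"bad orientation for {fn!r}: {self.orientations[fn]!r}")

    @property
    def functions(self) -> list[str]:
        return sorted(self.frame["scoring_function"].unique())

    def scores_for(self, scoring_function: str) -> pd.Series:
        sub = self.frame[self.frame["scoring_function"] == scoring_function]
        if sub.empty:
            raise KeyError(scoring_function)
        return sub.set_index("compound_id")["score"]

    @classmethod
    def from_csv(cls, path, orientations: Mapping[str, str] | None = None) -> "ScoreTable":
        return cls(pd.read_csv(path), orientations)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, columns=list(self.COLUMNS))


def aggregate_poses(structure_scores: ScoreTable, parent_map: Mapping[str, str]) -> ScoreTable:
    """Collapse prepared-structure scores to one score per parent compound.

    Multiple prepared structures (tautomers, protomers, stereoisomers) of the
    same parent keep the best score in the declared orientation: the maximum
    when higher is inhibitor-like, the minimum otherwise.
    """
    frame = structure_scores.frame.copy()
    orphans = sorted(set(frame["compound_id"]) - set(parent_map))
    if orphans:
        raise KeyError(f"structure ids without a parent mapping: {orphans[:5]}")
    frame["parent"] = frame["compound_id"].map(parent_map)
    rows = []
    for (parent, fn), grp in frame.groupby(["parent", "scoring_function"], sort=False):
        best = (grp["score"].max()
                if structure_scores.orientations[fn] == HIGHER_IS_INHIBITOR
                else grp["score"].min())
        rows.append({"compound_id": parent, "scoring_function": fn, "score": best})
    return ScoreTable(pd.DataFrame(rows), structure_scores.orientations)


@dataclass(frozen=True)
class BinnedDistribution:
    """Per-class histogram of scores over shared half-open bins [edge, edge+w)."""

    bin_edges: np.ndarray
    counts: Mapping[str, np.ndarray]
    rel_freq: Mapping[str, np.ndarray]

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


def bin_scores(scores: Sequence[float], labels: Sequence, bin_width: float,
               anchor: float = 0.0) -> BinnedDistribution:
    """Bin scores into half-open intervals aligned to ``anchor``.

    Bin edges are ``anchor + k*bin_width`` for integer k, covering
    [min(scores), max(scores)]; each score falls into exactly one bin.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    s = np.asarray(scores, dtype=float)
    y = as_binary(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    for cls, mask in ((INHIBITOR, y == 1.0), (NON_INHIBITOR, y == 0.0)):
        if mask.sum() == 0:
            raise ValueError(f"no scores for class {cls!r}")
    k_lo = int(np.floor((s.min() - anchor) / bin_width))
    k_hi = int(np.floor((s.max() - anchor) / bin_width)) + 1
    edges = anchor + bin_width * np.arange(k_lo, k_hi + 1)
    idx = np.floor((s - anchor) / bin_width).astype(int) - k_lo
    n_bins = len(edges) - 1
    counts, rel = {}, {}
    for cls, mask in ((INHIBITOR, y == 1.0), (NON_INHIBITOR, y == 0.0)):
        c = np.bincount(idx[mask], minlength=n_bins).astype(int)
        counts[cls] = c
        rel[cls] = c / c.sum()
    return BinnedDistribution(bin_edges=edges, counts=counts, rel_freq=rel)


@dataclass(frozen=True)
class ThresholdClassifier:
    """A fitted score threshold with orientation and provenance.

    Classification convention: the boundary score itself is called inhibitor
    (score >= threshold when higher is inhibitor-like, <= when lower is).
    """

    threshold: float
    orientation: str = HIGHER_IS_INHIBITOR
    provenance: str = "fixed"
    scoring_function_name: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def classify(self, scores) -> np.ndarray:
        return classify_by_threshold(scores, self)

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "ThresholdClassifier":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls(**json.loads(text))


def classify_by_threshold(scores, clf: ThresholdClassifier) -> np.ndarray:
    """Label scores against a threshold; NaN scores become ``unpredicted``."""
    s = np.asarray(scores, dtype=float)
    nan = np.isnan(s)
    if nan.any():
        logger.warning("%d compounds without a score reported as unpredicted", int(nan.sum()))
    if clf.orientation == HIGHER_IS_INHIBITOR:
        pred = (s >= clf.threshold).astype(float)
    else:
        pred = (s <= clf.threshold).astype(float)
    pred[nan] = np.nan
    return from_binary(pred, template=[INHIBITOR])


def _training_gmean(threshold: float, scores: np.ndarray, y: np.ndarray, orientation: str) -> float:
    pred = (scores >= threshold) if orientation == HIGHER_IS_INHIBITOR else (scores <= threshold)
    t = y.astype(bool)
    tp = int((pred & t).sum()); fn = int((~pred & t).sum())
    tn = int((~pred & ~t).sum()); fp = int((pred & ~t).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return float(np.sqrt(sens * spec))


def find_intersection(binned: BinnedDistribution, scores=None, labels=None,
                      orientation: str = HIGHER_IS_INHIBITOR,
                      scoring_function_name: str = "") -> ThresholdClassifier:
    """Threshold at the crossing of the class relative-frequency polylines.

    The per-class relative frequencies are treated as polylines over the bin
    centers and the crossing score is found by linear interpolation. When
    the curves cross more than once, the crossing whose threshold maximizes
    the G-mean on the training data (``scores``/``labels``, defaulting to a
    bin-level evaluation) is kept; ties go to the lowest score.
    """
    centers = binned.centers
    f_inh = np.asarray(binned.rel_freq[INHIBITOR], dtype=float)
    f_non = np.asarray(binned.rel_freq[NON_INHIBITOR], dtype=float)
    d = f_inh - f_non
    if np.allclose(d, 0.0):
        raise NoIntersectionError(
            "class frequency curves are identical; no usable intersection",
            centers=centers, freq_inhibitor=f_inh, freq_non_inhibitor=f_non,
        )
    # A crossing is either a sign change of the difference between adjacent
    # bins, or a bin where both class frequencies are equal and positive.
    # Empty bins (both classes zero) carry no curve: the gap between two
    # fully separated distributions is not a crossing.
    occupied = (f_inh > 0) | (f_non > 0)
    candidates: list[float] = []
    for i in range(len(d) - 1):
        a, b = d[i], d[i + 1]
        if occupied[i] and occupied[i + 1] and ((a < 0 < b) or (a > 0 > b)):
            frac = a / (a - b)
            candidates.append(float(centers[i] + frac * (centers[i + 1] - centers[i])))
    for i in np.flatnonzero((d == 0.0) & occupied):
        candidates.append(float(centers[i]))
    candidates = sorted(set(candidates))
    if not candidates:
        raise NoIntersectionError(
            "inhibitor and non-inhibitor frequency curves do not cross",
            centers=centers, freq_inhibitor=f_inh, freq_non_inhibitor=f_non,
        )
    if scores is None or labels is None:
        # bin-level surrogate: weight centers by class counts
        scores = np.repeat(centers, binned.counts[INHIBITOR] + binned.counts[NON_INHIBITOR])
        labels = np.concatenate([
            np.repeat([1.0, 0.0], [binned.counts[INHIBITOR][i], binned.counts[NON_INHIBITOR][i]])
            for i in range(binned.n_bins)
        ])
        y = labels
    else:
        scores = np.asarray(scores, dtype=float)
        y = as_binary(labels)
    best = max(candidates, key=lambda t: (_training_gmean(t, scores, y, orientation), -t))
    return ThresholdClassifier(threshold=best, orientation=orientation,
                               provenance="intersection_point",
                               scoring_function_name=scoring_function_name)


def bin_probability_table(binned: BinnedDistribution, yates: bool = False) -> pd.DataFrame:
    """Per-bin inhibitor probability and chi-square enrichment p-value.

    P(inhibitor | bin) is the raw count ratio within the bin. The p-value
    comes from the 2x2 table {in-bin vs out-of-bin} x {inhibitor vs
    non-inhibitor} with one degree of freedom (Yates correction off by
    default). Empty bins get a missing probability and p = 1 by convention.
    """
    n_inh = np.asarray(binned.counts[INHIBITOR])
    n_non = np.asarray(binned.counts[NON_INHIBITOR])
    tot_inh, tot_non = int(n_inh.sum()), int(n_non.sum())
    rows = []
    for i in range(binned.n_bins):
        a, b = int(n_inh[i]), int(n_non[i])
        in_bin = a + b
        if in_bin == 0:
            prob, chi2, p = np.nan, np.nan, 1.0
        else:
            prob = a / in_bin
            table = np.array([[a, b], [tot_inh - a, tot_non - b]])
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                chi2, p = 0.0, 1.0  # degenerate margin: no evidence of association
            else:
                chi2, p, _, _ = chi2_contingency(table, correction=yates)
        rows.append({
            "bin_low": binned.bin_edges[i], "bin_high": binned.bin_edges[i + 1],
            "n_inhibitor": a, "n_non_inhibitor": b,
            "p_inhibitor": prob, "chi2": chi2, "p_value": p,
        })
    return pd.DataFrame(rows)


def physchem_rule(mw, logp, mw_cut: float = 390.0, logp_cut: float = 3.6) -> np.ndarray:
    """MW/logP OR-rule: inhibitor iff MW >= mw_cut or logP >= logp_cut.

    Both cut-offs are inclusive. Returns labels (scalar in, scalar-like out).
    """
    mw_a = np.atleast_1d(np.asarray(mw, dtype=float))
    lp_a = np.atleast_1d(np.asarray(logp, dtype=float))
    pred = ((mw_a >= mw_cut) | (lp_a >= logp_cut)).astype(float)
    out = from_binary(pred, template=[INHIBITOR])
    if np.isscalar(mw) or np.ndim(mw) == 0:
        return out[0]
    return out


def fit_property_threshold(values, labels, bin_width: Optional[float] = None,
                           anchor: float = 0.0, name: str = "") -> ThresholdClassifier:
    """Fit an intersection-point threshold on a single molecular property.

    Uses the same binning + polyline-crossing machinery as the score models,
    with the higher-is-inhibitor orientation (heavier / more lipophilic
    compounds are the inhibitor-like end for this transporter). When
    ``bin_width`` is omitted, 1/40 of the observed range is used.
    """
    v = np.asarray(values, dtype=float)
    if bin_width is None:
        span = v.max() - v.min()
        if span == 0:
            raise NoIntersectionError("property is constant; no intersection exists")
        bin_width = span / 40.0
    binned = bin_scores(v, labels, bin_width=bin_width, anchor=anchor)
    return find_intersection(binned, scores=v, labels=labels,
                             orientation=HIGHER_IS_INHIBITOR, scoring_function_name=name)


def combined_score(score, mw, logp, normalization: Mapping[str, tuple[float, float]],
                   orientation: str = HIGHER_IS_INHIBITOR) -> np.ndarray:
    """Composite in [0, 1]: mean of min-max-normalized (score, MW, logP).

    The docking score is sign-adjusted first so that higher always means
    more inhibitor-like; each feature is scaled with the training (min, max)
    and clipped to [0, 1] before averaging.
    """
    s = np.asarray(score, dtype=float)
    if orientation == LOWER_IS_INHIBITOR:
        s = -s
    feats = {"score": s, "mw": np.asarray(mw, dtype=float), "logp": np.asarray(logp, dtype=float)}
    parts = []
    for key, x in feats.items():
        lo, hi = normalization[key]
        if hi <= lo:
            raise DegenerateFeatureError(f"zero-width normalization range for {key!r}")
        parts.append(np.clip((x - lo) / (hi - lo), 0.0, 1.0))
    return np.mean(parts, axis=0)


# --------------------------------------------------------------------------
# scikit-learn estimator surface
# --------------------------------------------------------------------------

class IntersectionClassifier(ClassifierMixin, BaseEstimator):
    """Intersection-point threshold classifier over a single score column.

    Parameters
    ----------
    bin_width : float, default 5.0
        Width of the score bins (5 suits GOLD-type scores; use ~1 for
        Glide/XScore-type scales, or refit on the property at hand).
    anchor : float, default 0.0
        Score value that bin edges are aligned to.
    orientation : str
        ``"higher_is_inhibitor"`` or ``"lower_is_inhibitor"``.
    scoring_function : str, optional
        Name recorded in the fitted ``ThresholdClassifier``.

    Attributes
    ----------
    threshold_ : float
        The fitted crossing score.
    classifier_ : ThresholdClassifier
    binned_ : BinnedDistribution
    """

    def __init__(self, bin_width: float = 5.0, anchor: float = 0.0,
                 orientation: str = HIGHER_IS_INHIBITOR, scoring_function: str = ""):
        self.bin_width = bin_width
        self.anchor = anchor
        self.orientation = orientation
        self.scoring_function = scoring_function

    @staticmethod
    def _scores(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2:
            if arr.shape[1] != 1:
                raise ValueError("expected a single score column")
            arr = arr[:, 0]
        return arr

    def fit(self, X, y):
        s = self._scores(X)
        self._y_template = np.asarray(y, dtype=object)
        self.binned_ = bin_scores(s, y, bin_width=self.bin_width, anchor=self.anchor)
        self.classifier_ = find_intersection(
            self.binned_, scores=s, labels=y, orientation=self.orientation,
            scoring_function_name=self.scoring_function,
        )
        self.threshold_ = self.classifier_.threshold
        self.classes_ = np.unique(self._y_template)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        s = self._scores(X)
        return s - self.threshold_ if self.orientation == HIGHER_IS_INHIBITOR \
            else self.threshold_ - s

    def predict(self, X):
        check_is_fitted(self, "threshold_")
        pred = classify_by_threshold(self._scores(X), self.classifier_)
        return from_binary(as_binary(pred, allow_unpredicted=True), template=self._y_template)


class PhyschemRuleClassifier(ClassifierMixin, BaseEstimator):
    """Fixed MW/logP OR-rule: inhibitor iff MW >= mw_cut or logP >= logp_cut.

    ``fit`` only records the label vocabulary; the cut-offs are parameters.
    Input ``X`` has two columns: MW (Da) then logP.
    """

    def __init__(self, mw_cut: float = 390.0, logp_cut: float = 3.6):
        self.mw_cut = mw_cut
        self.logp_cut = logp_cut

    def fit(self, X=None, y=None):
        self._y_template = (np.asarray(y, dtype=object)
                            if y is not None else np.array([INHIBITOR], dtype=object))
        self.classes_ = np.unique(self._y_template)
        self.is_fitted_ = True
        return self

    def predict(self, X):
        if not getattr(self, "is_fitted_", False):
            self.fit()
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("X must have columns (mw, logp)")
        pred = physchem_rule(arr[:, 0], arr[:, 1], self.mw_cut, self.logp_cut)
        return from_binary(as_binary(pred), template=self._y_template)


class CombinedScoreClassifier(ClassifierMixin, BaseEstimator):
    """Threshold model on the mean of normalized (docking score, MW, logP).

    Min-max ranges are fitted on the training data only; the composite lies
    in [0, 1] and an intersection-point threshold is fitted on it.
    """

    def __init__(self, bin_width: float = 0.05, orientation: str = HIGHER_IS_INHIBITOR):
        self.bin_width = bin_width
        self.orientation = orientation

    def _check_X(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("X must have columns (score, mw, logp)")
        return arr

    def fit(self, X, y):
        arr = self._check_X(X)
        self._y_template = np.asarray(y, dtype=object)
        s = -arr[:, 0] if self.orientation == LOWER_IS_INHIBITOR else arr[:, 0]
        self.normalization_ = {
            "score": (float(s.min()), float(s.max())),
            "mw": (float(arr[:, 1].min()), float(arr[:, 1].max())),
            "logp": (float(arr[:, 2].min()), float(arr[:, 2].max())),
        }
        composite = combined_score(arr[:, 0], arr[:, 1], arr[:, 2],
                                   self.normalization_, self.orientation)
        binned = bin_scores(composite, y, bin_width=self.bin_width, anchor=0.0)
        self.classifier_ = find_intersection(binned, scores=composite, labels=y,
                                             orientation=HIGHER_IS_INHIBITOR,
                                             scoring_function_name="combined")
        self.threshold_ = self.classifier_.threshold
        self.classes_ = np.unique(self._y_template)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "normalization_")
        arr = self._check_X(X)
        return combined_score(arr[:, 0], arr[:, 1], arr[:, 2],
                              self.normalization_, self.orientation)

    def predict(self, X):
        check_is_fitted(self, "threshold_")
        pred = classify_by_threshold(self.transform(X), self.classifier_)
        return from_binary(as_binary(pred, allow_unpredicted=True), template=self._y_template)
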