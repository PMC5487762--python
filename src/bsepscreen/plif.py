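"""Protein-ligand interaction fingerprints (PLIFs) built from contact records.

Contact detection from 3D poses is outside this package: the input is a flat
table of interaction records (compound, residue, interaction type, optional
ligand functional group and strength fraction). Three fingerprint flavors
are supported:

``residue``
    one bit per contacted residue,
``residue_type``
    one bit per (residue, interaction type) pair,
``residue_group``
    one bit per (residue, ligand functional group) pair.

Records whose strength falls below the configured minima (1% for molecular
interactions, 20% for surface contacts) are dropped before bit-setting;
records without a strength are kept.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .descriptors import tanimoto
from .labels import BINARY_LABELS, INHIBITOR, NON_INHIBITOR, as_binary, from_binary

logger = logging.getLogger(__name__)

__all__ = [
    "INTERACTION_TYPES",
    "FLAVORS",
    "InteractionRecord",
    "PLIF",
    "read_interaction_table",
    "build_universe",
    "build_plif",
    "build_plifs_by_compound",
    "interaction_frequency",
    "plif_heatmap_matrix",
    "plif_similarity_predict",
    "PlifNeighborClassifier",
]

INTERACTION_TYPES = frozenset(
    {"hydrophobic", "hbond_donor", "hbond_acceptor", "ionic", "surface_contact"}
)
FLAVORS = ("residue", "residue_type", "residue_group")

MIN_STRENGTH_MOLECULAR = 0.01
MIN_STRENGTH_SURFACE = 0.20

_RESIDUE_RE = re.compile(r"^([A-Za-z]{3})(\d+)$")


def parse_residue(residue: str) -> tuple[str, int]:
    """Split a label like ``Phe334`` into (code, number); number must be > 0."""
    m = _RESIDUE_RE.match(residue)
    if not m or int(m.group(2)) <= 0:
        raise ValueError(f"bad residue label {residue!r} (expected e.g. 'Phe334')")
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class InteractionRecord:
    """One ligand-residue contact."""

    compound_id: str
    residue: str
    interaction_type: str
    functional_group: Optional[str] = None
    strength: Optional[float] = None

    def __post_init__(self) -> None:
        parse_residue(self.residue)
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(
                f"unknown interaction type {self.interaction_type!r}; "
                f"expected one of {sorted(INTERACTION_TYPES)}"
            )
        if self.strength is not None and not (0.0 <= self.strength <= 1.0):
            raise ValueError(f"strength must be in [0, 1], got {self.strength}")

    def passes_strength(self, min_molecular: float = MIN_STRENGTH_MOLECULAR,
                        min_surface: float = MIN_STRENGTH_SURFACE) -> bool:
        if self.strength is None:
            return True
        floor = min_surface if self.interaction_type == "surface_contact" else min_molecular
        return self.strength >= floor

    def key(self, flavor: str):
        if flavor == "residue":
            return self.residue
        if flavor == "residue_type":
            return (self.residue, self.interaction_type)
        if flavor == "residue_group":
            return None if self.functional_group is None else (self.residue, self.functional_group)
        raise ValueError(f"unknown PLIF flavor {flavor!r}")


def read_interaction_table(path) -> list[InteractionRecord]:
    """Read records from CSV (or a JSON list of objects with the same fields)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        frame = pd.read_csv(path)
        missing = {"compound_id", "residue", "interaction_type"} - set(frame.columns)
        if missing:
            raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
        rows = frame.to_dict("records")
    records = []
    for row in rows:
        fg = row.get("functional_group")
        if isinstance(fg, float) and np.isnan(fg):
            fg = None
        strength = row.get("strength")
        if strength is not None and isinstance(strength, float) and np.isnan(strength):
            strength = None
        records.append(InteractionRecord(
            compound_id=str(row["compound_id"]), residue=str(row["residue"]),
            interaction_type=str(row["interaction_type"]),
            functional_group=None if fg is None else str(fg),
            strength=None if strength is None else float(strength),
        ))
    return records


def _sort_key(key):
    if isinstance(key, tuple):
        res, extra = key
        return (parse_residue(res)[1], res, extra)
    return (parse_residue(key)[1], key, "")


def build_universe(records: Iterable[InteractionRecord], flavor: str) -> tuple:
    """Fixed, ordered key universe for a fingerprint flavor from a record pool."""
    keys = {r.key(flavor) for r in records if r.passes_strength() and r.key(flavor) is not None}
    return tuple(sorted(keys, key=_sort_key))


@dataclass(frozen=True)
class PLIF:
    """Binary interaction fingerprint of one compound over a fixed universe."""

    flavor: str
    universe: tuple
    bits: frozenset

    def __post_init__(self) -> None:
        if self.flavor not in FLAVORS:
            raise ValueError(f"unknown PLIF flavor {self.flavor!r}")
        stray = self.bits - set(self.universe)
        if stray:
            raise ValueError(f"bits outside the universe: {sorted(stray, key=_sort_key)[:3]}")

    def to_vector(self) -> np.ndarray:
        return np.array([1 if k in self.bits else 0 for k in self.universe], dtype=np.uint8)

    def residues(self) -> frozenset:
        if self.flavor == "residue":
            return self.bits
        return frozenset(k[0] for k in self.bits)


def build_plif(records: Sequence[InteractionRecord], flavor: str, universe: tuple,
               min_strength_molecular: float = MIN_STRENGTH_MOLECULAR,
               min_strength_surface: float = MIN_STRENGTH_SURFACE) -> PLIF:
    """Build one compound's PLIF; a bit is set iff >= 1 record matches its key.

    All records must share one compound id. Keys observed in the records but
    absent from the fitted universe are ignored (they carry no bit).
    """
    ids = {r.compound_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple compounds: {sorted(ids)}")
    allowed = set(universe)
    bits = set()
    for r in records:
        if not r.passes_strength(min_strength_molecular, min_strength_surface):
            continue
        key = r.key(flavor)
        if key is not None and key in allowed:
            bits.add(key)
    return PLIF(flavor=flavor, universe=universe, bits=frozenset(bits))


def build_plifs_by_compound(records: Iterable[InteractionRecord], flavor: str,
                            universe: Optional[tuple] = None,
                            compound_ids: Optional[Iterable[str]] = None) -> dict[str, PLIF]:
    """Group records by compound and build one PLIF each.

    ``compound_ids`` lets compounds without any record receive an all-zero
    fingerprint. The universe defaults to one built from these records.
    """
    records = list(records)
    if universe is None:
        universe = build_universe(records, flavor)
    grouped: dict[str, list[InteractionRecord]] = {}
    for r in records:
        grouped.setdefault(r.compound_id, []).append(r)
    ids = list(compound_ids) if compound_ids is not None else sorted(grouped)
    return {cid: build_plif(grouped.get(cid, []), flavor, universe) for cid in ids}


def interaction_frequency(plifs: Mapping[str, PLIF], labels: Mapping[str, str],
                          interaction_type: str) -> pd.DataFrame:
    """Per-residue fraction of each class contacting via ``interaction_type``.

    Requires residue_type-flavor PLIFs. Returns a frame indexed by residue
    with columns ``inhibitor``, ``non_inhibitor`` (NaN for an empty class)
    and ``difference``, residues ordered by sequence number.
    """
    if interaction_type not in INTERACTION_TYPES:
        raise ValueError(f"unknown interaction type {interaction_type!r}")
    for p in plifs.values():
        if p.flavor != "residue_type":
            raise ValueError("interaction_frequency needs residue_type PLIFs")
    residues = sorted({k[0] for p in plifs.values() for k in p.universe
                       if k[1] == interaction_type}, key=_sort_key)
    members = {cls: [cid for cid in plifs if labels[cid] == cls] for cls in BINARY_LABELS}
    unknown = set(labels.values()) - set(BINARY_LABELS)
    if unknown:
        raise ValueError(f"labels must be binary activity classes, got {sorted(unknown)}")
    out = {}
    for col, cls in (("inhibitor", INHIBITOR), ("non_inhibitor", NON_INHIBITOR)):
        ids = members[cls]
        if not ids:
            out[col] = pd.Series(np.nan, index=residues, dtype=float)
        else:
            out[col] = pd.Series(
                {res: np.mean([(res, interaction_type) in plifs[cid].bits for cid in ids])
                 for res in residues})
    table = pd.DataFrame(out, index=residues)
    table["difference"] = table["inhibitor"] - table["non_inhibitor"]
    return table


def plif_heatmap_matrix(records: Iterable[InteractionRecord], labels: Mapping[str, str],
                        class_label: str = INHIBITOR) -> pd.DataFrame:
    """Residue x functional-group matrix of distinct-compound contact counts.

    Cell (r, g) counts compounds of ``class_label`` with at least one
    strength-passing record pairing residue r with ligand group g. Rows are
    ordered by residue number, columns alphabetically.
    """
    pairs: dict[tuple[str, str], set] = {}
    for r in records:
        if labels.get(r.compound_id) != class_label:
            continue
        if r.functional_group is None or not r.passes_strength():
            continue
        pairs.setdefault((r.residue, r.functional_group), set()).add(r.compound_id)
    if not pairs:
        return pd.DataFrame()
    residues = sorted({k[0] for k in pairs}, key=_sort_key)
    groups = sorted({k[1] for k in pairs})
    mat = pd.DataFrame(0, index=residues, columns=groups, dtype=int)
    for (res, grp), cids in pairs.items():
        mat.loc[res, grp] = len(cids)
    return mat


def plif_similarity_predict(query: PLIF, inhibitor_plifs: Sequence[PLIF],
                            decision_threshold: float = 0.5) -> tuple[str, float]:
    """Nearest-known-inhibitor prediction on PLIF bits.

    Returns (label, max Tanimoto similarity to any reference inhibitor);
    inhibitor iff the similarity reaches ``decision_threshold``.
    """
    if not inhibitor_plifs:
        raise ValueError("empty reference inhibitor set")
    qv = query.to_vector()
    for ref in inhibitor_plifs:
        if ref.flavor != query.flavor or ref.universe != query.universe:
            raise ValueError("query and reference PLIFs must share flavor and universe")
    best = max(tanimoto(qv, ref.to_vector()) for ref in inhibitor_plifs)
    label = INHIBITOR if best >= decision_threshold else NON_INHIBITOR
    return label, float(best)


class PlifNeighborClassifier(ClassifierMixin, BaseEstimator):
    """Max-Tanimoto-to-known-inhibitors classifier on PLIF bit vectors.

    ``fit`` keeps the fingerprints of the training inhibitors; ``predict``
    labels a query inhibitor when its best similarity to any of them reaches
    ``decision_threshold``. ``decision_function`` returns that similarity.
    """

    def __init__(self, decision_threshold: float = 0.5):
        self.decision_threshold = decision_threshold

    def fit(self, X, y):
        arr = np.asarray(X)
        yb = as_binary(y).astype(bool)
        if arr.ndim != 2 or arr.shape[0] != yb.size:
            raise ValueError("X must be (n_compounds, n_bits) aligned with y")
        self._y_template = np.asarray(y, dtype=object)
        self.reference_ = arr[yb].astype(bool)
        if self.reference_.shape[0] == 0:
            raise ValueError("no inhibitors in the training data")
        self.classes_ = np.unique(self._y_template)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "reference_")
        arr = np.asarray(X).astype(bool)
        sims = np.empty(arr.shape[0])
        for i, row in enumerate(arr):
            inter = (self.reference_ & row).sum(axis=1)
            union = (self.reference_ | row).sum(axis=1)
            with np.errstate(invalid="ignore"):
                s = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
            sims[i] = s.max()
        return sims

    def predict(self, X):
        sims = self.decision_function(X)
        pred = (sims >= self.decision_threshold).astype(float)
        return from_binary(pred, template=self._y_template)
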