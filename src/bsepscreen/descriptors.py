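"""Molecular descriptors: MW, logP, MACCS fingerprints, Tanimoto similarity
and functional-group SMARTS profiling.

logP is the Crippen atom-contribution estimate. Different atom-contribution
schemes disagree by up to about a log unit on lipophilic compounds, so
downstream thresholds (e.g. the 3.6 logP rule) should be refit when a
different estimator produced the training values.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, MACCSkeys

from .labels import BINARY_LABELS, INHIBITOR, NON_INHIBITOR

logger = logging.getLogger(__name__)

__all__ = [
    "InvalidStructureError",
    "GroupCatalog",
    "compute_mw",
    "compute_logp",
    "maccs_fingerprint",
    "tanimoto",
    "match_functional_groups",
    "group_frequency_profile",
    "presence_frequency_profile",
]

#: Length of an RDKit MACCS key vector (bit 0 is a placeholder, 166 real keys).
MACCS_NBITS = 167


class InvalidStructureError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"unparsable SMILES: {smiles!r}")
    return mol


def compute_mw(smiles: str) -> float:
    """Average-atomic-mass molecular weight in Da."""
    return Descriptors.MolWt(_mol(smiles))


def compute_logp(smiles: str) -> float:
    """Crippen atom-contribution octanol/water logP."""
    return Crippen.MolLogP(_mol(smiles))


def maccs_fingerprint(smiles: str) -> np.ndarray:
    """MACCS structural key fingerprint as a 0/1 uint8 vector of length 167."""
    fp = MACCSkeys.GenMACCSKeys(_mol(smiles))
    arr = np.zeros(MACCS_NBITS, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def tanimoto(fp_a: Sequence[int], fp_b: Sequence[int], zero_sentinel: float = 0.0) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two binary vectors.

    Two all-zero vectors have an undefined similarity; ``zero_sentinel`` is
    returned with a warning in that case.
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = int((a | b).sum())
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints is undefined; "
                      f"returning sentinel {zero_sentinel}", stacklevel=2)
        return zero_sentinel
    return int((a & b).sum()) / union


@dataclass(frozen=True)
class GroupCatalog:
    """Ordered catalog of named functional-group SMARTS patterns."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names in catalog")
        for name, smarts in self.entries:
            if Chem.MolFromSmarts(smarts) is None:
                raise ValueError(f"invalid SMARTS for group {name!r}: {smarts!r}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def patterns(self) -> dict[str, Chem.Mol]:
        return {name: Chem.MolFromSmarts(s) for name, s in self.entries}

    @classmethod
    def from_csv(cls, path) -> "GroupCatalog":
        """Load a two-column (name, smarts) CSV; '#' lines are comments."""
        text = Path(path).read_text()
        return cls._from_text(text)

    @classmethod
    def _from_text(cls, text: str) -> "GroupCatalog":
        lines = [l for l in text.splitlines() if l.strip() and not l.lstrip().startswith("#")]
        reader = csv.DictReader(io.StringIO("\n".join(lines)))
        if reader.fieldnames is None or not {"name", "smarts"} <= set(reader.fieldnames):
            raise ValueError("catalog CSV must have 'name' and 'smarts' columns")
        return cls(tuple((row["name"], row["smarts"]) for row in reader))

    @classmethod
    def default(cls) -> "GroupCatalog":
        """The packaged catalog of common functional groups."""
        text = resources.files("bsepscreen").joinpath("resources/functional_groups.csv").read_text()
        return cls._from_text(text)


def match_functional_groups(smiles: str, catalog: GroupCatalog) -> dict[str, int]:
    """Count distinct substructure matches of every catalog pattern."""
    mol = _mol(smiles)
    return {
        name: len(mol.GetSubstructMatches(pattern, uniquify=True))
        for name, pattern in catalog.patterns().items()
    }


def presence_frequency_profile(presence: pd.DataFrame, labels: Sequence[str]) -> pd.DataFrame:
    """Per-class fraction of molecules containing each group, from a boolean matrix.

    ``presence`` is compounds x groups (truthy = group present); rows align
    with ``labels``. Returns a frame indexed by group with columns
    ``inhibitor``, ``non_inhibitor`` (NaN for an empty class) and
    ``difference``, sorted by |difference| descending.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(presence):
        raise ValueError("labels must align with presence rows")
    unknown = set(labels) - set(BINARY_LABELS)
    if unknown:
        raise ValueError(f"labels must be inhibitor/non-inhibitor, got {sorted(unknown)}")
    out = {}
    for col, cls in (("inhibitor", INHIBITOR), ("non_inhibitor", NON_INHIBITOR)):
        mask = labels == cls
        if mask.sum() == 0:
            out[col] = pd.Series(np.nan, index=presence.columns)
        else:
            out[col] = presence.loc[mask].astype(bool).mean(axis=0)
    table = pd.DataFrame(out)
    table["difference"] = table["inhibitor"] - table["non_inhibitor"]
    return table.reindex(table["difference"].abs().sort_values(ascending=False).index)


def group_frequency_profile(compound_set, catalog: GroupCatalog) -> pd.DataFrame:
    """Fraction of molecules in each activity class containing each group.

    Presence means at least one substructure match. Every record must be
    labeled inhibitor or non-inhibitor.
    """
    rows, labels = [], []
    for record in compound_set:
        counts = match_functional_groups(record.smiles, catalog)
        rows.append({name: counts[name] >= 1 for name in catalog.names})
        labels.append(record.class_label)
    presence = pd.DataFrame(rows, index=[r.id for r in compound_set], columns=catalog.names)
    return presence_frequency_profile(presence, labels)
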