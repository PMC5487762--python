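"""Compound data model, activity-class assignment and dataset curation.

Activity classes follow the strong-inhibitor convention used for BSEP
inhibition data: a compound with mean IC50 <= 10 uM is an inhibitor, one
with mean IC50 > 300 uM a non-inhibitor, and anything in between is
excluded so that only well-separated classes enter model building.

Cross-set deduplication uses a canonical structure key obtained after a
minimal standardization pipeline (largest organic fragment, charge
neutralization where valence allows, canonical SMILES with stereochemistry
retained). Tautomer canonicalization is deliberately not part of the key.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from rdkit import Chem
from rdkit.Chem import SDWriter
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import RDLogger

from .labels import EXCLUDED, INHIBITOR, NON_INHIBITOR, UNKNOWN

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "CompoundSet",
    "assign_activity_class",
    "standardize_key",
    "deduplicate_against",
    "read_compound_table",
    "write_compound_table",
]

CSV_COLUMNS = ("id", "smiles", "ic50_um", "label", "source")


def assign_activity_class(ic50: float, inhibitor_cutoff: float = 10.0,
                          noninhibitor_cutoff: float = 300.0) -> str:
    """Assign an activity class from a mean IC50 in uM.

    Inhibitor for IC50 <= ``inhibitor_cutoff`` (inclusive), non-inhibitor for
    IC50 strictly above ``noninhibitor_cutoff``, excluded in between.
    """
    if not (ic50 > 0):
        raise ValueError(f"IC50 must be positive, got {ic50!r}")
    if not inhibitor_cutoff < noninhibitor_cutoff:
        raise ValueError("inhibitor_cutoff must be below noninhibitor_cutoff")
    if ic50 <= inhibitor_cutoff:
        return INHIBITOR
    if ic50 > noninhibitor_cutoff:
        return NON_INHIBITOR
    return EXCLUDED


@dataclass(frozen=True)
class CompoundRecord:
    """One chemical entity with structure, activity and provenance.

    ``pic50`` is -log10 of the molar IC50; when ``mean_ic50`` (uM) is given
    and ``pic50`` is not, it is derived as ``6 - log10(mean_ic50)``.
    """

    id: str
    smiles: str
    mean_ic50: Optional[float] = None
    pic50: Optional[float] = None
    class_label: str = UNKNOWN
    source: str = ""

    def __post_init__(self) -> None:
        if self.mean_ic50 is not None:
            if not (self.mean_ic50 > 0):
                raise ValueError(f"{self.id}: IC50 must be positive")
            if self.pic50 is None:
                object.__setattr__(self, "pic50", 6.0 - math.log10(self.mean_ic50))

    def with_label(self, inhibitor_cutoff: float = 10.0,
                   noninhibitor_cutoff: float = 300.0) -> "CompoundRecord":
        """Return a copy whose class label is assigned from its IC50."""
        if self.mean_ic50 is None:
            return self
        label = assign_activity_class(self.mean_ic50, inhibitor_cutoff, noninhibitor_cutoff)
        return replace(self, class_label=label)


class CompoundSet:
    """Ordered collection of compound records with unique ids."""

    def __init__(self, records: Iterable[CompoundRecord], name: str = ""):
        self.records = list(records)
        self.name = name
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, key):
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.class_label] = counts.get(r.class_label, 0) + 1
        return counts

    def with_labels(self, inhibitor_cutoff: float = 10.0,
                    noninhibitor_cutoff: float = 300.0) -> "CompoundSet":
        return CompoundSet(
            [r.with_label(inhibitor_cutoff, noninhibitor_cutoff) for r in self.records],
            name=self.name,
        )

    def subset(self, labels: Iterable[str]) -> "CompoundSet":
        keep = set(labels)
        return CompoundSet([r for r in self.records if r.class_label in keep], name=self.name)


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_key(smiles: str) -> Optional[str]:
    """Canonical structure key: largest fragment, neutralized, stereo retained.

    Returns None for unparsable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    mol = _FRAGMENT_CHOOSER.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    return Chem.MolToSmiles(mol)


def deduplicate_against(reference: CompoundSet, target: CompoundSet) -> CompoundSet:
    """Remove from ``target`` every record whose structure key occurs in ``reference``.

    Order is preserved and the inputs are untouched. Unparsable structures in
    either set are skipped with a logged warning (those in ``target`` are kept,
    since they cannot be shown to overlap).
    """
    ref_keys = set()
    for r in reference:
        key = standardize_key(r.smiles)
        if key is None:
            logger.warning("reference %s: unparsable SMILES %r skipped", r.id, r.smiles)
        else:
            ref_keys.add(key)
    kept = []
    for r in target:
        key = standardize_key(r.smiles)
        if key is None:
            logger.warning("target %s: unparsable SMILES %r kept unchecked", r.id, r.smiles)
            kept.append(r)
        elif key not in ref_keys:
            kept.append(r)
    return CompoundSet(kept, name=target.name)


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "sdf", "smi"):
        return suffix
    raise ValueError(f"cannot infer compound table format from {path.name!r}")


def read_compound_table(path, fmt: Optional[str] = None, name: str = "",
                        ic50_property: str = "IC50_uM") -> CompoundSet:
    """Read a compound table from CSV, SDF or SMILES file.

    CSV needs ``id`` and ``smiles`` columns; ``ic50_um``, ``label`` and
    ``source`` are optional. SDF reads the IC50 from the property tag named
    by ``ic50_property``.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    records: list[CompoundRecord] = []
    if fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            cols = reader.fieldnames or []
            for col in ("id", "smiles"):
                if col not in cols:
                    raise ValueError(f"{path.name}: missing mandatory column {col!r}")
            for row in reader:
                ic50 = row.get("ic50_um")
                records.append(CompoundRecord(
                    id=row["id"],
                    smiles=row["smiles"],
                    mean_ic50=float(ic50) if ic50 not in (None, "") else None,
                    class_label=row.get("label") or UNKNOWN,
                    source=row.get("source") or "",
                ))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("%s: molecule %d unparsable, skipped", path.name, i)
                continue
            props = mol.GetPropsAsDict()
            cid = str(props.get("id", mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"))
            ic50 = props.get(ic50_property)
            records.append(CompoundRecord(
                id=cid or f"mol{i}",
                smiles=Chem.MolToSmiles(mol),
                mean_ic50=float(ic50) if ic50 is not None else None,
                class_label=str(props.get("label", UNKNOWN)),
                source=str(props.get("source", "")),
            ))
    elif fmt == "smi":
        with open(path) as fh:
            for i, line in enumerate(fh):
                parts = line.split()
                if not parts:
                    continue
                records.append(CompoundRecord(
                    id=parts[1] if len(parts) > 1 else f"mol{i}",
                    smiles=parts[0],
                ))
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return CompoundSet(records, name=name or path.stem)


def write_compound_table(cset: CompoundSet, path, fmt: Optional[str] = None,
                         ic50_property: str = "IC50_uM") -> None:
    """Write a compound table; round-trips ids, structures, labels and IC50s."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(CSV_COLUMNS))
            writer.writeheader()
            for r in cset:
                writer.writerow({
                    "id": r.id, "smiles": r.smiles,
                    "ic50_um": "" if r.mean_ic50 is None else repr(r.mean_ic50),
                    "label": r.class_label, "source": r.source,
                })
    elif fmt == "sdf":
        writer = SDWriter(str(path))
        try:
            for r in cset:
                mol = Chem.MolFromSmiles(r.smiles)
                if mol is None:
                    logger.warning("%s: unparsable SMILES, not written to SDF", r.id)
                    continue
                mol.SetProp("_Name", r.id)
                mol.SetProp("id", r.id)
                if r.mean_ic50 is not None:
                    mol.SetProp(ic50_property, repr(r.mean_ic50))
                mol.SetProp("label", r.class_label)
                if r.source:
                    mol.SetProp("source", r.source)
                writer.write(mol)
        finally:
            writer.close()
    elif fmt == "smi":
        with open(path, "w") as fh:
            for r in cset:
                fh.write(f"{r.smiles}\t{r.id}\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}")
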