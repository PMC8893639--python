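"""Reading, canonicalizing, deduplicating and merging labeled molecule collections.

Molecules carry a source tag (``background`` or ``epitope``) and two boolean
assay labels: ``label_b`` (positive in a B-cell assay) and ``label_t``
(positive in a T-cell assay).  All structures are canonicalized with RDKit on
entry, so canonical SMILES is the identity key throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import ConfigurationError, EmptySetError, SmilesParseError

logger = logging.getLogger(__name__)

# RDKit prints its own parse diagnostics on stderr; errors are surfaced as
# structured SmilesParseError instead.
RDLogger.DisableLog("rdApp.error")

SOURCE_BACKGROUND = "background"
SOURCE_EPITOPE = "epitope"

_TRUE_STRINGS = {"1", "true", "yes", "t"}
_FALSE_STRINGS = {"0", "false", "no", "f", "", "nan", "none"}


@dataclass(frozen=True)
class Molecule:
    """A canonical structure record with source tag and B/T assay labels."""

    mol_id: str
    smiles: str
    source: str = SOURCE_BACKGROUND
    label_b: bool = False
    label_t: bool = False

    def __post_init__(self):
        if self.source == SOURCE_BACKGROUND and (self.label_b or self.label_t):
            raise ValueError(
                f"background molecule {self.mol_id!r} cannot carry a positive assay label"
            )


@dataclass
class MoleculeSet:
    """An ordered collection of molecules, unique by canonical SMILES."""

    molecules: list[Molecule] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self):
        return iter(self.molecules)

    def __getitem__(self, i):
        return self.molecules[i]

    @property
    def smiles(self) -> list[str]:
        return [m.smiles for m in self.molecules]

    def labels(self, assay: str) -> list[bool]:
        """Label vector for ``assay`` in {'b', 't'}."""
        if assay == "b":
            return [m.label_b for m in self.molecules]
        if assay == "t":
            return [m.label_t for m in self.molecules]
        raise ValueError(f"unknown assay {assay!r}; expected 'b' or 't'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mol_id": [m.mol_id for m in self.molecules],
                "smiles": [m.smiles for m in self.molecules],
                "source": [m.source for m in self.molecules],
                "label_b": [m.label_b for m in self.molecules],
                "label_t": [m.label_t for m in self.molecules],
            }
        )

    def to_csv(self, path) -> None:
        """Canonical CSV dump for provenance."""
        self.to_frame().to_csv(path, index=False)


@dataclass
class LoadReport:
    accepted: int = 0
    rejected: int = 0
    rejected_records: list[str] = field(default_factory=list)


def canonical_smiles(smiles_text: str) -> str:
    """Canonical SMILES of ``smiles_text``; raises SmilesParseError if invalid."""
    if not smiles_text or not smiles_text.strip():
        raise SmilesParseError(smiles_text, "empty string")
    mol = Chem.MolFromSmiles(smiles_text)
    if mol is None:
        raise SmilesParseError(smiles_text)
    return Chem.MolToSmiles(mol)


def parse_smiles(
    smiles_text: str,
    mol_id: str | None = None,
    source: str = SOURCE_BACKGROUND,
    label_b: bool = False,
    label_t: bool = False,
) -> Molecule:
    """Parse one SMILES into a Molecule with the canonical form as its smiles field.

    Canonicalization is a fixed point: parsing the returned smiles again yields
    the same string.
    """
    canon = canonical_smiles(smiles_text)
    return Molecule(
        mol_id=mol_id if mol_id is not None else canon,
        smiles=canon,
        source=source,
        label_b=label_b,
        label_t=label_t,
    )


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return bool(value) and not pd.isna(value)
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise ConfigurationError(f"cannot interpret {value!r} as a boolean label")


def _records_from_csv(path: Path, smiles_column: str, id_column: str | None):
    df = pd.read_csv(path, dtype=str)
    if smiles_column not in df.columns:
        raise ConfigurationError(
            f"CSV {path} lacks required SMILES column {smiles_column!r} "
            f"(columns present: {list(df.columns)})"
        )
    for i, row in df.iterrows():
        rec_id = None
        if id_column and id_column in df.columns and not pd.isna(row[id_column]):
            rec_id = str(row[id_column])
        lb = _parse_bool(row["label_b"]) if "label_b" in df.columns else False
        lt = _parse_bool(row["label_t"]) if "label_t" in df.columns else False
        src = str(row["source"]) if "source" in df.columns and not pd.isna(row["source"]) else None
        yield str(row[smiles_column]), rec_id, lb, lt, src


def _records_from_smi(path: Path):
    # one record per line: SMILES, optionally followed by an identifier
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            rec_id = parts[1].strip() if len(parts) > 1 else None
            yield smiles, rec_id, False, False, None


def _records_from_sdf(path: Path, label_b_prop: str, label_t_prop: str):
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            yield None, f"sdf_record_{i}", False, False, None
            continue
        rec_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else None
        lb = _parse_bool(mol.GetProp(label_b_prop)) if mol.HasProp(label_b_prop) else False
        lt = _parse_bool(mol.GetProp(label_t_prop)) if mol.HasProp(label_t_prop) else False
        yield Chem.MolToSmiles(mol), rec_id, lb, lt, None


def load_dataset(
    path,
    format: str | None = None,
    source: str = SOURCE_BACKGROUND,
    smiles_column: str = "smiles",
    id_column: str | None = "id",
    label_b_prop: str = "label_b",
    label_t_prop: str = "label_t",
) -> tuple[MoleculeSet, LoadReport]:
    """Load a molecule collection from CSV, SMI or SDF.

    ``format`` defaults to the file suffix.  ``source`` is the default source
    tag; a CSV ``source`` column (as written by MoleculeSet.to_csv) overrides
    it per record.  Every record with a parsable structure becomes a
    Molecule; unparsable records are counted in the returned LoadReport.
    Raises EmptySetError if no record is parsable.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        records = _records_from_csv(path, smiles_column, id_column)
    elif fmt == "smi":
        records = _records_from_smi(path)
    elif fmt == "sdf":
        records = _records_from_sdf(path, label_b_prop, label_t_prop)
    else:
        raise ConfigurationError(f"unsupported format {fmt!r}; expected csv, smi or sdf")

    report = LoadReport()
    molecules: list[Molecule] = []
    for i, (smiles, rec_id, lb, lt, rec_source) in enumerate(records):
        src = rec_source or source
        if lb or lt:
            src = SOURCE_EPITOPE
        if src == SOURCE_BACKGROUND:
            lb = lt = False
        try:
            if smiles is None:
                raise SmilesParseError("<unreadable SDF record>")
            mol = parse_smiles(
                smiles,
                mol_id=rec_id if rec_id is not None else f"{path.stem}_{i}",
                source=src,
                label_b=lb,
                label_t=lt,
            )
        except SmilesParseError:
            report.rejected += 1
            report.rejected_records.append(str(smiles))
            continue
        molecules.append(mol)
        report.accepted += 1

    if not molecules:
        raise EmptySetError(f"no parsable records in {path}")
    logger.info("loaded %s: %d accepted, %d rejected", path, report.accepted, report.rejected)
    return MoleculeSet(molecules, provenance=f"loaded from {path} ({fmt})"), report


def _merge_pair(keep: Molecule, other: Molecule) -> Molecule:
    """OR-merge labels of two molecules with the same canonical SMILES.

    The first occurrence wins for mol_id; a molecule positive in any record is
    positive.  Source becomes 'epitope' if either copy is an epitope.
    """
    label_b = keep.label_b or other.label_b
    label_t = keep.label_t or other.label_t
    source = (
        SOURCE_EPITOPE
        if SOURCE_EPITOPE in (keep.source, other.source) or label_b or label_t
        else SOURCE_BACKGROUND
    )
    return replace(keep, source=source, label_b=label_b, label_t=label_t)


def deduplicate(ms: MoleculeSet) -> MoleculeSet:
    """One Molecule per canonical SMILES; labels of duplicates OR-merged.

    Idempotent; preserves first-occurrence order and mol_id.
    """
    by_smiles: dict[str, Molecule] = {}
    order: list[str] = []
    for mol in ms.molecules:
        if mol.smiles in by_smiles:
            by_smiles[mol.smiles] = _merge_pair(by_smiles[mol.smiles], mol)
        else:
            by_smiles[mol.smiles] = mol
            order.append(mol.smiles)
    return MoleculeSet([by_smiles[s] for s in order], provenance=ms.provenance)


def merge_background_positives(background: MoleculeSet, positives: MoleculeSet) -> MoleculeSet:
    """Union of a background set and a positive (epitope) set.

    A canonical SMILES present in both keeps the positive labels and
    source='epitope'; the background copy is dropped.  Both inputs are assumed
    individually deduplicated; the result is deduplicated by construction.
    """
    positive_smiles = {m.smiles: m for m in positives.molecules}
    merged: list[Molecule] = []
    for mol in background.molecules:
        if mol.smiles in positive_smiles:
            continue  # positive label wins; background copy dropped
        merged.append(mol)
    merged.extend(positives.molecules)
    return MoleculeSet(
        merged,
        provenance=f"merge({background.provenance!r}, {positives.provenance!r})",
    )


def from_records(
    records: Iterable[tuple[str, bool, bool]],
    source_rule: str = "auto",
    id_prefix: str = "mol",
) -> MoleculeSet:
    """Build a MoleculeSet from (smiles, label_b, label_t) triples.

    With source_rule='auto', any molecule with a positive label is tagged
    'epitope', the rest 'background'.
    """
    mols = []
    for i, (smi, lb, lt) in enumerate(records):
        src = SOURCE_EPITOPE if (lb or lt) else SOURCE_BACKGROUND
        mols.append(parse_smiles(smi, mol_id=f"{id_prefix}_{i}", source=src, label_b=lb, label_t=lt))
    return MoleculeSet(mols)
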