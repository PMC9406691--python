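"""Readers and writers for the delimited-table interfaces.

Datasets are delimited text (CSV or TSV by extension) with header columns
``id, smiles, activity[, split]``; attribute profiles are written long-form
(``molecule_id, key, category, count``); models round-trip through JSON.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd

from .records import AttributeProfile, MoleculeRecord
from .smiles_attributes import SmilesError, canonize_smiles

log = logging.getLogger("cwqsar")


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_dataset(path: str | Path) -> list[MoleculeRecord]:
    """Load molecules, canonizing SMILES and flagging duplicates.

    Malformed rows raise with their line number; duplicate canonical SMILES
    emit a warning naming both record ids.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    required = {"id", "smiles"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: header must contain {sorted(required)}")

    records: list[MoleculeRecord] = []
    seen: dict[str, str] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            smiles = canonize_smiles(str(row["smiles"]))
        except SmilesError as exc:
            raise ValueError(f"{path}:{line}: {exc}") from exc
        activity = None
        if "activity" in df.columns and pd.notna(row["activity"]):
            try:
                activity = float(row["activity"])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{line}: bad activity {row['activity']!r}"
                ) from exc
        split = (
            str(row["split"])
            if "split" in df.columns and pd.notna(row.get("split"))
            else None
        )
        mol_id = str(row["id"])
        if smiles in seen:
            warnings.warn(
                f"{path}:{line}: {mol_id} duplicates molecule "
                f"{seen[smiles]} (same canonical SMILES)"
            )
        else:
            seen[smiles] = mol_id
        records.append(MoleculeRecord(mol_id, smiles, activity, split))
    return records


def write_dataset(records: list[MoleculeRecord], path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "id": [r.molecule_id for r in records],
            "smiles": [r.smiles for r in records],
            "activity": [r.activity for r in records],
            "split": [r.split for r in records],
        }
    ).to_csv(path, sep=_sep(path), index=False)


def write_profiles(profiles: list[AttributeProfile], path: str | Path) -> None:
    """Long-format attribute table: molecule_id, key, category, count."""
    path = Path(path)
    rows = [
        {
            "molecule_id": p.molecule_id,
            "key": k.key,
            "category": k.category,
            "count": n,
        }
        for p in profiles
        for k, n in sorted(p.counts.items(), key=lambda kv: (kv[0].category, kv[0].key))
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def read_profiles(path: str | Path) -> list[AttributeProfile]:
    from .records import AttributeKey

    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    profiles: dict[str, AttributeProfile] = {}
    for _, row in df.iterrows():
        prof = profiles.setdefault(
            str(row["molecule_id"]), AttributeProfile(str(row["molecule_id"]))
        )
        prof.add(AttributeKey(row["key"], row["category"]), int(row["count"]))
    return list(profiles.values())


def read_descriptor_matrix(path: str | Path) -> pd.DataFrame:
    """CSV descriptor matrix: first column id, header of descriptor names."""
    path = Path(path)
    return pd.read_csv(path, sep=_sep(path), index_col=0)
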