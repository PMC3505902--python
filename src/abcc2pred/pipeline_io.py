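"""Reading and writing the chemical and tabular formats the pipeline touches.

Structures come in as SD files (V2000 connection tables) or SMILES lists;
activity arrives as a CSV keyed on the compound identifier.  Parsing is
tolerant: a malformed entry is logged and skipped, never fatal, and every
reader returns a report stating exactly what was skipped so counts always
reconcile.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .records import Dataset, MoleculeRecord

logger = logging.getLogger(__name__)


class EmptyInputError(ValueError):
    """Raised when a structure file yields zero parseable records."""


@dataclass
class ParseReport:
    """What the structure reader skipped, by entry index."""

    n_input: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)

    @property
    def n_parsed(self) -> int:
        return self.n_input - self.n_skipped


@dataclass
class JoinReport:
    """Diagnostics of the structure/activity join."""

    matched: list[str] = field(default_factory=list)
    unmatched_records: list[str] = field(default_factory=list)
    unmatched_table_ids: list[str] = field(default_factory=list)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".sdf", ".sd", ".mol"}:
        return "sdf"
    if suffix in {".smi", ".smiles", ".txt"}:
        return "smiles"
    raise ValueError(f"cannot infer structure format from {path.name!r}")


def read_structures(
    path: str | Path, fmt: str | None = None
) -> tuple[list[MoleculeRecord], ParseReport]:
    """Read an SD file (V2000) or SMILES list into molecule records.

    SMILES files hold one record per line: the SMILES string, optionally
    followed by whitespace and an identifier.  SD records are identified by
    their title line or, failing that, an ``id``/``ID``/``NSC`` property.
    Entries that fail to parse are logged with their index and skipped.

    Returns the records together with a :class:`ParseReport`; raises
    :class:`EmptyInputError` if nothing parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "sdf":
        records, report = _read_sdf(path)
    elif fmt == "smiles":
        records, report = _read_smiles(path)
    else:
        raise ValueError(f"unknown structure format {fmt!r}")
    if not records:
        raise EmptyInputError(f"{path}: no parseable records")
    if report.n_skipped:
        logger.warning(
            "%s: skipped %d of %d entries", path.name, report.n_skipped, report.n_input
        )
    return records, report


def _read_sdf(path: Path) -> tuple[list[MoleculeRecord], ParseReport]:
    text = path.read_text()
    if "V3000" in text:
        raise ValueError(
            f"{path}: V3000 connection tables are not supported; "
            "convert to V2000 first"
        )
    report = ParseReport()
    records: list[MoleculeRecord] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for i, mol in enumerate(supplier):
        report.n_input += 1
        if mol is None:
            report.skipped.append((i, "unparseable molblock"))
            logger.warning("%s: skipping molblock %d (unparseable)", path.name, i)
            continue
        rid = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        if not rid:
            for key in ("id", "ID", "NSC"):
                if mol.HasProp(key):
                    rid = mol.GetProp(key).strip()
                    break
        if not rid:
            rid = f"SDF_{i}"
        pcc = float(mol.GetProp("pcc")) if mol.HasProp("pcc") else None
        records.append(MoleculeRecord(id=rid, mol=mol, pcc=pcc))
    return records, report


def _read_smiles(path: Path) -> tuple[list[MoleculeRecord], ParseReport]:
    report = ParseReport()
    records: list[MoleculeRecord] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            report.n_input += 1
            parts = line.split(None, 1)
            smiles = parts[0]
            rid = parts[1].strip() if len(parts) > 1 else f"SMI_{i}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                report.skipped.append((i, f"invalid SMILES {smiles!r}"))
                logger.warning("%s: skipping line %d (invalid SMILES)", path.name, i)
                continue
            records.append(MoleculeRecord(id=rid, mol=mol))
    return records, report


def read_activity_table(path: str | Path) -> pd.DataFrame:
    """Read an ``id,pcc`` CSV (header required, UTF-8).

    Raises on duplicate identifiers or non-numeric PCC entries, naming the
    offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns or "pcc" not in df.columns:
        raise ValueError(f"{path}: activity table must have columns id,pcc")
    dupes = df["id"][df["id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicated id(s) in activity table: {list(dupes)}")
    pcc = pd.to_numeric(df["pcc"], errors="coerce")
    bad = df.index[pcc.isna() & df["pcc"].notna()]
    if len(bad):
        row = int(bad[0])
        raise ValueError(
            f"{path}: non-numeric pcc {df['pcc'].iloc[row]!r} at row {row + 2}"
        )
    df["pcc"] = pcc
    return df


def join_activity(
    records: list[MoleculeRecord], table: str | Path | pd.DataFrame
) -> tuple[list[MoleculeRecord], JoinReport]:
    """Attach PCC values to records by exact identifier match.

    Identifiers are compared as exact strings (no numeric normalization, so
    ``"0123"`` and ``"123"`` stay distinct).  Unmatched identifiers on
    either side are collected in the returned :class:`JoinReport`.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_activity_table(table)
    else:
        dupes = table["id"][table["id"].duplicated()].unique()
        if len(dupes):
            raise ValueError(f"duplicated id(s) in activity table: {list(dupes)}")
    pcc_by_id = dict(zip(table["id"].astype(str), table["pcc"].astype(float)))
    report = JoinReport()
    record_ids = set()
    for rec in records:
        record_ids.add(rec.id)
        if rec.id in pcc_by_id:
            rec.pcc = float(pcc_by_id[rec.id])
            report.matched.append(rec.id)
        else:
            report.unmatched_records.append(rec.id)
    report.unmatched_table_ids = [i for i in pcc_by_id if i not in record_ids]
    if report.unmatched_records or report.unmatched_table_ids:
        logger.info(
            "activity join: %d matched, %d records without activity, "
            "%d table ids without structure",
            len(report.matched),
            len(report.unmatched_records),
            len(report.unmatched_table_ids),
        )
    return records, report


def write_dataset(ds: Dataset, path: str | Path, fmt: str | None = None) -> Path:
    """Write a dataset as SDF (V2000, with ``pcc``/``label`` properties) or CSV.

    Round-trip safe: reading the SDF back preserves identifiers, atom/bond
    counts, formal charges and PCC values.  2D coordinates are regenerated
    for SDF output only; descriptors never consume them.
    """
    path = Path(path)
    if len(ds) == 0:
        raise ValueError("refusing to write an empty dataset")
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in {".sdf", ".sd"} else "csv"
    if fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for i, rec in enumerate(ds.records):
                mol = Chem.Mol(rec.mol)
                AllChem.Compute2DCoords(mol)
                mol.SetProp("_Name", rec.id)
                if rec.pcc is not None:
                    mol.SetProp("pcc", repr(rec.pcc))
                if ds.labels is not None:
                    mol.SetProp("label", str(ds.labels[i]))
                writer.write(mol)
        finally:
            writer.close()
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["id", "pcc"] + (["label"] if ds.labels is not None else [])
            header.append("smiles")
            w.writerow(header)
            for i, rec in enumerate(ds.records):
                row = [rec.id, "" if rec.pcc is None else repr(rec.pcc)]
                if ds.labels is not None:
                    row.append(str(ds.labels[i]))
                row.append(rec.smiles)
                w.writerow(row)
    else:
        raise ValueError(f"unknown output format {fmt!r}")
    return path
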