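"""Core in-memory containers: a compound record and a labeled dataset."""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem


@dataclass
class MoleculeRecord:
    """One compound: identifier, 2D molecular graph, activity, provenance.

    Parameters
    ----------
    id : str
        Compound identifier (e.g. an NSC number).  Must be non-empty.
    mol : rdkit.Chem.Mol
        The molecular graph.  2D only; stereochemistry is cleared during
        curation.
    pcc : float or None
        Pearson correlation coefficient between the compound's cytotoxicity
        profile and transporter mRNA expression, in [-1, 1].  ``None`` until
        an activity table has been joined.
    provenance : list of str
        Ordered curation-step annotations (e.g. ``"mixture:stripped HCl"``).
    """

    id: str
    mol: Chem.Mol
    pcc: float | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.mol is None or self.mol.GetNumAtoms() == 0:
            raise ValueError(f"record {self.id!r}: molecule has no atoms")
        if self.pcc is not None and not (-1.0 <= self.pcc <= 1.0):
            raise ValueError(
                f"record {self.id!r}: pcc {self.pcc} outside [-1, 1]"
            )

    @property
    def smiles(self) -> str:
        """Canonical SMILES of the current structure."""
        return Chem.MolToSmiles(self.mol)

    def annotate(self, note: str) -> None:
        self.provenance.append(note)


SUBSTRATE = 1
NON_SUBSTRATE = 0


@dataclass
class Dataset:
    """An ordered compound collection, optionally labeled by a PCC cutoff.

    ``labels`` aligns 1:1 with ``records`` (1 = substrate, 0 =
    non-substrate); ``label_threshold`` records the PCC cutoff used.
    """

    records: list[MoleculeRecord]
    label_threshold: float | None = None
    labels: list[int] | None = None

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.records):
            raise ValueError(
                f"{len(self.labels)} labels for {len(self.records)} records"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_substrates(self) -> int:
        if self.labels is None:
            raise ValueError("dataset is not labeled")
        return int(sum(self.labels))

    @property
    def n_non_substrates(self) -> int:
        return len(self.records) - self.n_substrates

    def validate_unique_ids(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise ValueError(f"duplicate record id {r.id!r}")
            seen.add(r.id)
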