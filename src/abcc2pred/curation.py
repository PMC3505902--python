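"""Multistep structure curation for QSAR-ready compound libraries.

The protocol follows the now-standard ordered cleaning recipe for
cheminformatics datasets:

1. remove inorganics (no carbon atom),
2. resolve mixtures (keep the single organic component of organic/inorganic
   salts; delete multi-organic mixtures),
3. remove organometallics,
4. remove compounds with elements outside the descriptor-computable set
   (e.g. Se, Te),
5. standardize chemotypes (clear stereo, normalize functional groups,
   neutralize, canonical tautomer),
6. remove duplicates (conflicting activity values delete the whole group),
7. remove permanently charged compounds (net formal charge != 0).

An optional protonation variant then assigns physiological charge states to
strong acids and bases.  Every step reports what it removed and why, and the
report's counts are required to reconcile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from . import config
from .records import Dataset, MoleculeRecord

logger = logging.getLogger(__name__)


@dataclass
class CurationConfig:
    allowed_elements: frozenset[str] = config.ALLOWED_ELEMENTS
    metal_elements: frozenset[str] = config.METAL_ELEMENTS
    pcc_duplicate_tolerance: float = 1e-6
    charge_variant: str = "neutral"  # or "charged"
    tautomer_ruleset: str = config.TAUTOMER_RULESET

    def __post_init__(self) -> None:
        overlap = self.allowed_elements & self.metal_elements
        if overlap:
            raise ValueError(f"allowed and metal element sets overlap: {overlap}")
        if self.charge_variant not in {"neutral", "charged"}:
            raise ValueError(f"unknown charge_variant {self.charge_variant!r}")


@dataclass
class StepReport:
    step: str
    n_input: int
    removed: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class CurationReport:
    steps: list[StepReport] = field(default_factory=list)

    @property
    def initial_count(self) -> int:
        return self.steps[0].n_input if self.steps else 0

    @property
    def final_count(self) -> int:
        return self.steps[-1].n_output if self.steps else 0

    @property
    def total_removed(self) -> int:
        return sum(s.n_removed for s in self.steps)

    def validate(self) -> None:
        """Check count conservation across consecutive steps."""
        for prev, nxt in zip(self.steps, self.steps[1:]):
            if nxt.n_input != prev.n_output:
                raise AssertionError(
                    f"count mismatch: {prev.step} output {prev.n_output} != "
                    f"{nxt.step} input {nxt.n_input}"
                )
        if self.final_count != self.initial_count - self.total_removed:
            raise AssertionError("final count does not reconcile with removals")

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "step": s.step,
                    "n_input": s.n_input,
                    "n_removed": s.n_removed,
                    "removed": [{"id": i, "reason": r} for i, r in s.removed],
                }
                for s in self.steps
            ],
            "initial_count": self.initial_count,
            "final_count": self.final_count,
        }


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def remove_inorganics(
    records: list[MoleculeRecord],
) -> tuple[list[MoleculeRecord], StepReport]:
    """Step 1: drop records whose structure contains no carbon atom."""
    report = StepReport("remove_inorganics", len(records))
    kept = []
    for rec in records:
        if _has_carbon(rec.mol):
            kept.append(rec)
        else:
            report.removed.append((rec.id, "inorganic: no carbon atom"))
    return kept, report


def resolve_mixture(rec: MoleculeRecord) -> tuple[MoleculeRecord | None, str | None]:
    """Step 2 on one record: strip inorganic counter-ions, reject
    multi-organic mixtures.

    Retained iff exactly one disconnected component contains carbon; that
    component becomes the record's structure.  Returns ``(record, None)`` or
    ``(None, reason)``.
    """
    frags = Chem.GetMolFrags(rec.mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return rec, None
    organic = [f for f in frags if _has_carbon(f)]
    if len(organic) == 1:
        stripped = organic[0]
        Chem.SanitizeMol(stripped)
        rec.mol = stripped
        rec.annotate(f"mixture: kept organic component, stripped {len(frags) - 1} fragment(s)")
        return rec, None
    if len(organic) == 0:
        return None, "mixture: no organic component"
    return None, f"mixture: {len(organic)} organic components"


def resolve_mixtures(
    records: list[MoleculeRecord],
) -> tuple[list[MoleculeRecord], StepReport]:
    report = StepReport("resolve_mixtures", len(records))
    kept = []
    for rec in records:
        out, reason = resolve_mixture(rec)
        if out is not None:
            kept.append(out)
        else:
            report.removed.append((rec.id, reason))
    return kept, report


def remove_organometallics(
    records: list[MoleculeRecord], cfg: CurationConfig | None = None
) -> tuple[list[MoleculeRecord], StepReport]:
    """Step 3: drop records containing any metal atom."""
    cfg = cfg or CurationConfig()
    report = StepReport("remove_organometallics", len(records))
    kept = []
    for rec in records:
        metals = {
            a.GetSymbol() for a in rec.mol.GetAtoms() if a.GetSymbol() in cfg.metal_elements
        }
        if metals:
            report.removed.append((rec.id, f"organometallic: contains {sorted(metals)}"))
        else:
            kept.append(rec)
    return kept, report


def remove_special_atoms(
    records: list[MoleculeRecord], cfg: CurationConfig | None = None
) -> tuple[list[MoleculeRecord], StepReport]:
    """Step 4: drop records with elements outside the computable set."""
    cfg = cfg or CurationConfig()
    report = StepReport("remove_special_atoms", len(records))
    kept = []
    for rec in records:
        bad = {
            a.GetSymbol()
            for a in rec.mol.GetAtoms()
            if a.GetSymbol() not in cfg.allowed_elements
        }
        if bad:
            report.removed.append((rec.id, f"special atoms: {sorted(bad)}"))
        else:
            kept.append(rec)
    return kept, report


_NORMALIZER = rdMolStandardize.Normalizer()
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMERIZER = rdMolStandardize.TautomerEnumerator()


def standardize(rec: MoleculeRecord) -> tuple[MoleculeRecord | None, str | None]:
    """Step 5: clear stereo, normalize chemotypes, neutralize, canonical
    tautomer.

    Idempotent: standardizing an already-standard record returns an
    identical canonical structure.  Sanitization failures (impossible
    valences) remove the record with a reason.
    """
    try:
        mol = Chem.Mol(rec.mol)
        Chem.RemoveStereochemistry(mol)
        mol = rdMolStandardize.Cleanup(mol)
        mol = _NORMALIZER.normalize(mol)
        mol = _UNCHARGER.uncharge(mol)
        mol = _TAUTOMERIZER.Canonicalize(mol)
        Chem.SanitizeMol(mol)
    except Exception as exc:  # noqa: BLE001 - any toolkit failure removes the record
        return None, f"standardization failed: {exc}"
    rec.mol = mol
    return rec, None


def standardize_all(
    records: list[MoleculeRecord],
) -> tuple[list[MoleculeRecord], StepReport]:
    report = StepReport("standardize", len(records))
    kept = []
    for rec in records:
        out, reason = standardize(rec)
        if out is not None:
            kept.append(out)
        else:
            report.removed.append((rec.id, reason))
    return kept, report


def deduplicate(
    records: list[MoleculeRecord], tolerance: float = 1e-6
) -> tuple[list[MoleculeRecord], StepReport]:
    """Step 6: collapse or delete structural duplicates.

    Identity is the canonical structure string of the standardized record.
    A duplicate group whose PCC values all agree within ``tolerance`` keeps
    its first-occurring entry; a group with conflicting values is deleted
    wholly (the activity is unreliable).  Missing PCC values conflict with
    numeric ones.
    """
    report = StepReport("deduplicate", len(records))
    groups: dict[str, list[MoleculeRecord]] = {}
    order: list[str] = []
    for rec in records:
        key = rec.smiles
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    kept = []
    for key in order:
        group = groups[key]
        if len(group) == 1:
            kept.append(group[0])
            continue
        pccs = [r.pcc for r in group]
        if any(p is None for p in pccs):
            consistent = all(p is None for p in pccs)
        else:
            consistent = max(pccs) - min(pccs) <= tolerance
        if consistent:
            first = group[0]
            first.annotate(f"deduplicate: kept 1 of {len(group)} identical entries")
            kept.append(first)
            for rec in group[1:]:
                report.removed.append((rec.id, "duplicate: identical structure and PCC"))
        else:
            for rec in group:
                report.removed.append((rec.id, "duplicate: conflicting PCC values"))
    return kept, report


def remove_permanent_charges(
    records: list[MoleculeRecord],
) -> tuple[list[MoleculeRecord], StepReport]:
    """Step 7: drop records with non-zero net formal charge.

    Runs after neutralization, so anything still charged is permanent
    (e.g. quaternary ammonium).  Zwitterions with net charge 0 survive: the
    rule tests the net charge only.
    """
    report = StepReport("remove_permanent_charges", len(records))
    kept = []
    for rec in records:
        q = Chem.GetFormalCharge(rec.mol)
        if q == 0:
            kept.append(rec)
        else:
            report.removed.append((rec.id, f"permanent net charge {q:+d}"))
    return kept, report


def assign_charge_states(records: list[MoleculeRecord]) -> list[MoleculeRecord]:
    """Protonation variant: ionize strong acids and bases.

    Substructure-rule based, no pKa model: carboxylic, sulfonic, sulfinic,
    sulfate/sulfamate and phosphorus oxyacid hydroxyls are deprotonated to
    -1 each (one ionization per phosphorus); aliphatic amines, amidines and
    guanidines are protonated to +1 each.  Amides, anilines and aromatic
    ring nitrogens are untouched.
    """
    out = []
    for rec in records:
        mol = Chem.RWMol(rec.mol)
        changed = 0
        deprotonated: set[int] = set()
        for name, smarts in config.STRONG_ACID_SMARTS.items():
            patt = Chem.MolFromSmarts(smarts)
            site = config.STRONG_ACID_SITE_INDEX[name]
            for match in mol.GetSubstructMatches(patt):
                idx = match[site]
                if idx in deprotonated:
                    continue
                atom = mol.GetAtomWithIdx(idx)
                if atom.GetFormalCharge() == 0 and atom.GetTotalNumHs() >= 1:
                    atom.SetFormalCharge(-1)
                    atom.SetNumExplicitHs(max(0, atom.GetNumExplicitHs()))
                    atom.SetNoImplicit(False)
                    _drop_one_hydrogen(atom)
                    deprotonated.add(idx)
                    changed += 1
        protonated: set[int] = set()
        for name, smarts in config.STRONG_BASE_SMARTS.items():
            patt = Chem.MolFromSmarts(smarts)
            site = config.STRONG_BASE_SITE_INDEX[name]
            for match in mol.GetSubstructMatches(patt):
                idx = match[site]
                if idx in protonated or idx in deprotonated:
                    continue
                atom = mol.GetAtomWithIdx(idx)
                if atom.GetFormalCharge() == 0:
                    atom.SetFormalCharge(+1)
                    atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                    protonated.add(idx)
                    changed += 1
        if changed:
            m = mol.GetMol()
            Chem.SanitizeMol(m)
            rec.mol = m
            rec.annotate(f"charge assignment: {changed} site(s) ionized")
        out.append(rec)
    return out


def _drop_one_hydrogen(atom: Chem.Atom) -> None:
    if atom.GetNumExplicitHs() > 0:
        atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
    # otherwise the implicit-H count adjusts automatically on sanitize


def run_curation(
    records: list[MoleculeRecord], cfg: CurationConfig | None = None
) -> tuple[Dataset, CurationReport]:
    """Apply curation steps 1-7 in order; optionally assign charge states.

    The printed order matters: mixtures are resolved before the metal check
    so an organic/metal-salt pair survives with its counter-ion stripped.
    The returned report always satisfies count conservation.
    """
    cfg = cfg or CurationConfig()
    report = CurationReport()

    # work on copies: curation rewrites structures (desalting,
    # standardization) and must not mutate the caller's records
    records = [
        MoleculeRecord(
            id=r.id, mol=Chem.Mol(r.mol), pcc=r.pcc, provenance=list(r.provenance)
        )
        for r in records
    ]

    records, step = remove_inorganics(records)
    report.steps.append(step)
    records, step = resolve_mixtures(records)
    report.steps.append(step)
    records, step = remove_organometallics(records, cfg)
    report.steps.append(step)
    records, step = remove_special_atoms(records, cfg)
    report.steps.append(step)
    records, step = standardize_all(records)
    report.steps.append(step)
    records, step = deduplicate(records, cfg.pcc_duplicate_tolerance)
    report.steps.append(step)
    records, step = remove_permanent_charges(records)
    report.steps.append(step)

    if cfg.charge_variant == "charged":
        records = assign_charge_states(records)

    report.validate()
    ds = Dataset(records=list(records))
    ds.validate_unique_ids()
    logger.info(
        "curation: %d -> %d records (%d removed)",
        report.initial_count,
        report.final_count,
        report.total_removed,
    )
    return ds, report
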