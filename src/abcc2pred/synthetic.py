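"""Synthetic compound libraries with a known activity-generating signal.

The generator assembles small organic molecules from a seeded fragment
grammar (aromatic and aliphatic scaffolds decorated with halogen, hydroxyl,
amino, carboxyl, sulfo, nitro and thiomethyl substituents) and assigns each
a Pearson-correlation activity value

    pcc = beta0 + b1*z(PEOE_VSA_FNEG) + b2*z(vsa_don) + b3*z(SlogP_VSA0) + eps

with negative coefficients, Gaussian noise, and the intercept calibrated so
that a target fraction of the library (default 13%, matching the class
imbalance of the real transporter data this emulates) falls at or below the
-0.25 substrate cutoff.  The signal enters through descriptors reported as
discriminative for anion-transporter substrates — fractional negative
surface charge, H-bond-donor surface area and low-logP surface area — so
recovering them downstream is a meaningful test of the whole pipeline.

Deliberately dirty records (inorganics, mixtures, organometallics,
selenium compounds, permanent cations, conflicting duplicates) can be
appended, each annotated with its intended curation fate, so the curation
protocol can be tested record by record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .curation import standardize
from .descriptors import compute_descriptors
from .pipeline_io import write_dataset
from .records import Dataset, MoleculeRecord

SIGNAL_DESCRIPTORS = ("PEOE_VSA_FNEG", "vsa_don", "SlogP_VSA0")

_SCAFFOLDS = [
    "c1ccccc1",          # benzene
    "c1ccc2ccccc2c1",    # naphthalene
    "c1ccncc1",          # pyridine
    "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC", "CCCCCCCC",  # chains
]

#: substituent fragments; atom 0 is the attachment point
_SUBSTITUENTS = {
    "chloro": "Cl",
    "bromo": "Br",
    "hydroxyl": "O",
    "amino": "N",
    "carboxyl": "C(=O)O",
    "sulfo": "S(=O)(=O)O",
    "nitro": "[N+](=O)[O-]",
    "thiomethyl": "SC",
}


@dataclass
class DirtyConfig:
    """How many deliberately dirty records of each category to emit."""

    n_inorganic: int = 2
    n_mixture: int = 2
    n_salt: int = 1
    n_organometallic: int = 2
    n_special_atom: int = 1
    n_permanent_ion: int = 1
    n_duplicate_conflict_pairs: int = 1

    def __post_init__(self) -> None:
        for f in self.__dataclass_fields__:
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    @property
    def n_records(self) -> int:
        return (
            self.n_inorganic + self.n_mixture + self.n_salt
            + self.n_organometallic + self.n_special_atom
            + self.n_permanent_ion + 2 * self.n_duplicate_conflict_pairs
        )


@dataclass
class SimulationConfig:
    n_compounds: int = 2000
    seed: int = 0
    substrate_fraction: float = 0.13
    label_threshold: float = -0.25
    betas: tuple[float, float, float] = (-0.15, -0.10, -0.08)
    noise_sd: float = 0.15
    calibration_tolerance: float = 0.02
    dirty: DirtyConfig = field(default_factory=DirtyConfig)

    def __post_init__(self) -> None:
        if self.n_compounds <= 0:
            raise ValueError("n_compounds must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 < self.substrate_fraction < 1.0):
            raise ValueError("substrate_fraction must be in (0, 1)")


@dataclass
class SyntheticLibrary:
    records: list[MoleculeRecord]   # clean + dirty, in emission order
    truth: dict
    config: SimulationConfig

    @property
    def clean_records(self) -> list[MoleculeRecord]:
        dirty_ids = set(self.truth["dirty"])
        return [r for r in self.records if r.id not in dirty_ids]


def _assemble_molecule(rng: np.random.Generator) -> Chem.Mol | None:
    scaffold = Chem.MolFromSmiles(_SCAFFOLDS[rng.integers(len(_SCAFFOLDS))])
    sites = [
        a.GetIdx()
        for a in scaffold.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
    ]
    n_subs = int(rng.integers(0, 5))  # 0..4 substituents
    n_subs = min(n_subs, len(sites))
    chosen_sites = rng.choice(len(sites), size=n_subs, replace=False)
    names = sorted(_SUBSTITUENTS)
    mol = scaffold
    offset_sites = [sites[int(i)] for i in chosen_sites]
    for site in offset_sites:
        sub_name = names[int(rng.integers(len(names)))]
        frag = Chem.MolFromSmiles(_SUBSTITUENTS[sub_name])
        combined = Chem.RWMol(Chem.CombineMols(mol, frag))
        combined.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
        try:
            mol = combined.GetMol()
            Chem.SanitizeMol(mol)
        except Exception:  # noqa: BLE001 - invalid decoration: resample
            return None
    return mol


def _generate_clean(
    n: int, rng: np.random.Generator
) -> tuple[list[MoleculeRecord], list[str]]:
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    stall = 0
    max_stall = 3000  # consecutive failures to produce a new unique structure
    while len(records) < n:
        if stall > max_stall:
            raise RuntimeError(
                f"fragment grammar exhausted: only {len(records)} of {n} "
                "unique structures reachable; reduce n_compounds"
            )
        mol = _assemble_molecule(rng)
        if mol is None:
            stall += 1
            continue
        rec = MoleculeRecord(id=f"SYN{len(records):05d}", mol=mol)
        std, reason = standardize(
            MoleculeRecord(id=rec.id, mol=Chem.Mol(mol))
        )
        if std is None:
            stall += 1
            continue
        key = std.smiles
        if key in seen:
            stall += 1
            continue
        seen.add(key)
        stall = 0
        records.append(rec)
    return records, sorted(seen)


def make_dirty_fixtures(
    dirty: DirtyConfig | None = None, start_index: int = 0
) -> list[tuple[MoleculeRecord, str]]:
    """Dirty records with machine-readable expected curation fates.

    Fates: ``remove:<reason>`` records must be deleted by curation;
    ``keep:desalted`` records survive with their counter-ion stripped.
    Structures are chosen outside the clean grammar's reach (saturated
    carbocycles, metals, selenium) so they never collide with generated
    clean compounds.
    """
    dirty = dirty or DirtyConfig()
    catalog: list[tuple[str, str, float | None]] = []  # smiles, fate, pcc
    inorganics = ["[Na+].[Cl-]", "OS(=O)(=O)O", "O", "N"]
    for i in range(dirty.n_inorganic):
        catalog.append((inorganics[i % len(inorganics)], "remove:inorganic", 0.05))
    mixtures = ["c1ccccc1.Cc1ccccc1", "OCC.OCCC", "CC(=O)OC.CCOC(C)=O"]
    for i in range(dirty.n_mixture):
        catalog.append((mixtures[i % len(mixtures)], "remove:mixture", -0.10))
    salts = ["NC1CCCCC1.Cl", "OC(=O)C1CCCC1.[Na+].[Cl-]"]
    for i in range(dirty.n_salt):
        catalog.append((salts[i % len(salts)], "keep:desalted", -0.05))
    organometallics = ["C[Hg]Cl", "CC[Pb](CC)(CC)CC", "C[Sn](C)(C)C"]
    for i in range(dirty.n_organometallic):
        catalog.append(
            (organometallics[i % len(organometallics)], "remove:organometallic", 0.10)
        )
    specials = ["C[Se]CCC(N)C(=O)O", "c1ccc([Te]C)cc1", "C[As](C)C"]
    for i in range(dirty.n_special_atom):
        catalog.append((specials[i % len(specials)], "remove:special_atom", -0.30))
    ions = ["C[N+](C)(C)C", "C[n+]1ccccc1C"]
    for i in range(dirty.n_permanent_ion):
        catalog.append((ions[i % len(ions)], "remove:permanent_charge", -0.40))
    dup_structures = ["OC1CCCCC1", "CC1CCCC1O", "OCC1CCCCC1"]
    for i in range(dirty.n_duplicate_conflict_pairs):
        s = dup_structures[i % len(dup_structures)]
        catalog.append((s, "remove:duplicate_conflict", -0.40))
        catalog.append((s, "remove:duplicate_conflict", -0.10))
    out = []
    for j, (smiles, fate, pcc) in enumerate(catalog):
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # all catalog entries parse; guard regardless
            raise RuntimeError(f"dirty catalog entry failed to parse: {smiles}")
        rec = MoleculeRecord(id=f"DIRTY{start_index + j:03d}", mol=mol, pcc=pcc)
        out.append((rec, fate))
    return out


def generate_library(
    config: SimulationConfig | None = None, out_dir: str | Path | None = None
) -> SyntheticLibrary:
    """Generate a synthetic library: structures, activities and truth.

    Returns the records (clean first, dirty appended) with PCC values
    attached, plus a truth dictionary recording the generative
    coefficients, the achieved substrate fraction and the intended fate of
    every dirty record.  With ``out_dir`` set, writes ``structures.sdf``,
    ``activity.csv`` and ``truth.json`` (byte-identical across reruns with
    the same config).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    records, _ = _generate_clean(config.n_compounds, rng)

    # descriptor signal on the assembled structures
    sig = np.array(
        [
            [compute_descriptors(r)[d] for d in SIGNAL_DESCRIPTORS]
            for r in records
        ],
        dtype=float,
    )
    mean = sig.mean(axis=0)
    sd = sig.std(axis=0, ddof=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    z = (sig - mean) / sd
    eps = rng.normal(0.0, config.noise_sd, size=len(records))
    signal = z @ np.asarray(config.betas) + eps
    # calibrate the intercept so the substrate count hits the target:
    # place the k-th smallest signal exactly at the (inclusive) threshold
    k = max(1, round(config.substrate_fraction * len(records)))
    beta0 = config.label_threshold - float(np.sort(signal)[k - 1])
    pcc = np.clip(beta0 + signal, -1.0, 1.0)
    achieved = float((pcc <= config.label_threshold).mean())
    if abs(achieved - config.substrate_fraction) > config.calibration_tolerance:
        raise RuntimeError(
            f"substrate-fraction calibration failed: achieved {achieved:.3f} "
            f"vs target {config.substrate_fraction:.3f}; increase n_compounds "
            "or noise_sd"
        )
    for rec, value in zip(records, pcc):
        rec.pcc = float(value)

    dirty_pairs = make_dirty_fixtures(config.dirty)
    truth = {
        "seed": int(config.seed),
        "n_clean": len(records),
        "betas": list(config.betas),
        "beta0": beta0,
        "noise_sd": config.noise_sd,
        "signal_descriptors": list(SIGNAL_DESCRIPTORS),
        "label_threshold": config.label_threshold,
        "achieved_substrate_fraction": achieved,
        "dirty": {rec.id: fate for rec, fate in dirty_pairs},
    }
    all_records = records + [rec for rec, _ in dirty_pairs]
    library = SyntheticLibrary(records=all_records, truth=truth, config=config)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ds = Dataset(records=all_records)
        write_dataset(ds, out_dir / "structures.sdf", fmt="sdf")
        with open(out_dir / "activity.csv", "w") as fh:
            fh.write("id,pcc\n")
            for rec in all_records:
                fh.write(f"{rec.id},{rec.pcc!r}\n")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return library
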