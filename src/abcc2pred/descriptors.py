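"""2D descriptor panel, Z-score normalization and structural-key fingerprints.

The panel is the classic connection-table VSA family plus simple counts:

* ``PEOE_VSA*`` — per-atom van der Waals surface area (Labute's
  connection-table approximation) summed over atoms binned by
  Gasteiger-Marsili (PEOE) partial charge.  Charges and areas are computed
  on the explicit-hydrogen graph, so hydrogens contribute their own area
  and charge.
* ``SlogP_VSA*`` / ``SMR_VSA*`` — heavy-atom surface area (attached
  hydrogens' area folded into the heavy atom) binned by the Wildman-Crippen
  atomic logP / molar-refractivity contribution.
* pharmacophore-typed areas (``vsa_don``, ``vsa_other``) and counts
  (``a_don``, ``vsa_base``, halogen/heteroatom counts, bonds, rings, TPSA).

All descriptors are deterministic functions of the canonical connection
table; no 3D information is used anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, MACCSkeys, rdMolDescriptors

from . import config
from .records import MoleculeRecord

#: PEOE damping iterations (pinned; the classic iterative charge-equalization
#: scheme converges geometrically and six passes reproduce the published
#: charges to ~1e-3).
GASTEIGER_ITERATIONS = 6

#: half-open [lo, hi) PEOE charge bins of the printed panel
PEOE_BINS_TABLE3 = {
    "PEOE_VSA+1": (0.05, 0.10),
    "PEOE_VSA+2": (0.10, 0.15),
    "PEOE_VSA+3": (0.15, 0.20),
    "PEOE_VSA+4": (0.20, 0.25),
}
#: the remaining charge bins of the extended panel; together with the four
#: printed bins these tile the whole charge axis, so bin sums conserve the
#: total molecular surface area
PEOE_BINS_EXTENDED = {
    "PEOE_VSA+0": (0.00, 0.05),
    "PEOE_VSA+5": (0.25, 0.30),
    "PEOE_VSA+6": (0.30, math.inf),
    "PEOE_VSA-0": (-0.05, 0.00),
    "PEOE_VSA-1": (-0.10, -0.05),
    "PEOE_VSA-2": (-0.15, -0.10),
    "PEOE_VSA-3": (-0.20, -0.15),
    "PEOE_VSA-4": (-0.25, -0.20),
    "PEOE_VSA-5": (-0.30, -0.25),
    "PEOE_VSA-6": (-math.inf, -0.25 - 0.05),
}

#: logP-contribution bins, (lo, hi] except the open-ended first bin
SLOGP_BINS = {
    "SlogP_VSA0": (-math.inf, -0.40),
    "SlogP_VSA1": (-0.40, -0.20),
}
SLOGP_BINS_EXTENDED = {
    "SlogP_VSA2": (-0.20, 0.00),
    "SlogP_VSA3": (0.00, 0.10),
    "SlogP_VSA4": (0.10, 0.15),
    "SlogP_VSA5": (0.15, 0.20),
    "SlogP_VSA6": (0.20, 0.25),
    "SlogP_VSA7": (0.25, math.inf),
}

# Molar-refractivity bins, (lo, hi] on the sorted pair of the printed
# bounds.  The printed bounds are negative while Wildman-Crippen MR atomic
# contributions are non-negative, so on real chemistry these columns are
# constant zero and get flagged by the z-scorer; they are kept for panel
# completeness and documented as such.
SMR_BINS = {
    "SMR_VSA1": (-0.26, -0.11),
    "SMR_VSA2": (-0.35, -0.26),
    "SMR_VSA4": (-0.44, -0.39),
}

TABLE3_PANEL = [
    "a_don", "a_nBr", "a_nCl", "a_nN", "a_nO", "a_nS", "b_count",
    "PEOE_VSA+1", "PEOE_VSA+2", "PEOE_VSA+3", "PEOE_VSA+4",
    "PEOE_VSA_FNEG", "PEOE_VSA_FPOS", "PEOE_VSA_POS", "PEOE_VSA_PPOS",
    "rings",
    "SlogP_VSA0", "SlogP_VSA1",
    "SMR_VSA1", "SMR_VSA2", "SMR_VSA4",
    "TPSA",
    "vsa_base", "vsa_don", "vsa_other",
]

EXTENDED_EXTRAS = (
    list(PEOE_BINS_EXTENDED)
    + list(SLOGP_BINS_EXTENDED)
    + ["PEOE_VSA_NEG", "VSA_total", "a_count", "a_heavy", "a_acc", "a_aro",
       "b_rotN", "Weight"]
)
EXTENDED_PANEL = TABLE3_PANEL + EXTENDED_EXTRAS

#: polar-positive threshold: atoms with PEOE charge above this are "polar
#: positive", consistent with the upper edge of the printed charge bins
PPOS_CHARGE_THRESHOLD = 0.20

_BASIC_N_PATTERNS = [
    (Chem.MolFromSmarts(s), config.STRONG_BASE_SITE_INDEX[name])
    for name, s in config.STRONG_BASE_SMARTS.items()
]
_ACID_O_PATTERNS = [
    (Chem.MolFromSmarts(s), config.STRONG_ACID_SITE_INDEX[name])
    for name, s in config.STRONG_ACID_SMARTS.items()
]


class DescriptorError(ValueError):
    """Raised when a descriptor cannot be computed for a structure."""


def _atom_surface_areas(mol_h: Chem.Mol) -> np.ndarray:
    # all hydrogens are explicit here, so every atom owns its contribution
    # and the per-implicit-H constant returned alongside is irrelevant
    contribs, _ = rdMolDescriptors._CalcLabuteASAContribs(mol_h)
    return np.asarray(list(contribs), dtype=float)


def _gasteiger_charges(mol_h: Chem.Mol, rec_id: str) -> np.ndarray:
    AllChem.ComputeGasteigerCharges(mol_h, nIter=GASTEIGER_ITERATIONS)
    q = np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in mol_h.GetAtoms()], dtype=float
    )
    if not np.all(np.isfinite(q)):
        bad = [
            f"{a.GetSymbol()}#{a.GetIdx()}"
            for a, qi in zip(mol_h.GetAtoms(), q)
            if not np.isfinite(qi)
        ]
        raise DescriptorError(
            f"record {rec_id!r}: PEOE charge undefined for atom(s) {bad}; "
            "the element is outside the charge parameterization"
        )
    return q


def _match_atoms(mol: Chem.Mol, patterns) -> set[int]:
    hits: set[int] = set()
    for patt, site in patterns:
        for match in mol.GetSubstructMatches(patt):
            hits.add(match[site])
    return hits


def compute_descriptors(
    record: MoleculeRecord | Chem.Mol, panel: str = "table3"
) -> dict[str, float]:
    """Compute the named 2D descriptor vector for one curated compound.

    ``panel`` is ``"table3"`` (the 25 modelling descriptors) or
    ``"extended"`` (adds the remaining charge/logP bins and simple counts).
    Deterministic: the same canonical structure always yields a bitwise
    identical vector.
    """
    if panel not in {"table3", "extended"}:
        raise ValueError(f"unknown panel {panel!r}")
    mol = record.mol if isinstance(record, MoleculeRecord) else record
    rec_id = record.id if isinstance(record, MoleculeRecord) else "<mol>"

    mol_h = Chem.AddHs(mol)
    areas = _atom_surface_areas(mol_h)
    charges = _gasteiger_charges(mol_h, rec_id)
    total_vsa = float(areas.sum())

    out: dict[str, float] = {}

    # --- simple counts ----------------------------------------------------
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    out["a_nBr"] = float(symbols.count("Br"))
    out["a_nCl"] = float(symbols.count("Cl"))
    out["a_nN"] = float(symbols.count("N"))
    out["a_nO"] = float(symbols.count("O"))
    out["a_nS"] = float(symbols.count("S"))
    out["a_don"] = float(
        sum(
            1
            for a in mol.GetAtoms()
            if a.GetAtomicNum() in (7, 8) and a.GetTotalNumHs() >= 1
        )
    )
    out["b_count"] = float(mol_h.GetNumBonds())
    out["rings"] = float(rdMolDescriptors.CalcNumRings(mol))
    out["TPSA"] = float(rdMolDescriptors.CalcTPSA(mol))

    # --- PEOE charge-binned surface areas ---------------------------------
    bins = dict(PEOE_BINS_TABLE3)
    if panel == "extended":
        bins.update(PEOE_BINS_EXTENDED)
    for name, (lo, hi) in bins.items():
        mask = (charges >= lo) & (charges < hi)
        out[name] = float(areas[mask].sum())
    pos = float(areas[charges > 0].sum())
    neg = float(areas[charges < 0].sum())
    out["PEOE_VSA_POS"] = pos
    out["PEOE_VSA_FPOS"] = pos / total_vsa if total_vsa > 0 else 0.0
    out["PEOE_VSA_FNEG"] = neg / total_vsa if total_vsa > 0 else 0.0
    out["PEOE_VSA_PPOS"] = float(areas[charges > PPOS_CHARGE_THRESHOLD].sum())
    if panel == "extended":
        out["PEOE_VSA_NEG"] = neg
        out["VSA_total"] = total_vsa

    # --- heavy-atom areas with attached hydrogens folded in ---------------
    heavy_area = np.zeros(mol.GetNumAtoms())
    for atom in mol_h.GetAtoms():
        i = atom.GetIdx()
        if atom.GetAtomicNum() == 1:
            nbr = atom.GetNeighbors()[0].GetIdx()
            if nbr < len(heavy_area):
                heavy_area[nbr] += areas[i]
        elif i < len(heavy_area):
            heavy_area[i] += areas[i]

    crippen = rdMolDescriptors._CalcCrippenContribs(mol)
    logp_c = np.array([c[0] for c in crippen])
    mr_c = np.array([c[1] for c in crippen])

    slogp_bins = dict(SLOGP_BINS)
    if panel == "extended":
        slogp_bins.update(SLOGP_BINS_EXTENDED)
    for name, (lo, hi) in slogp_bins.items():
        mask = (logp_c > lo) & (logp_c <= hi)
        out[name] = float(heavy_area[mask].sum())
    for name, (lo, hi) in SMR_BINS.items():
        mask = (mr_c > lo) & (mr_c <= hi)
        out[name] = float(heavy_area[mask].sum())

    # --- pharmacophore-typed areas and counts -----------------------------
    basic_n = _match_atoms(mol, _BASIC_N_PATTERNS)
    acid_o = _match_atoms(mol, _ACID_O_PATTERNS)
    out["vsa_base"] = float(len(basic_n))
    # pure donors: N-H nitrogens (an O-H oxygen is simultaneously an
    # acceptor by the typing rules, so it is not a *pure* donor)
    donor_n = {
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 7 and a.GetTotalNumHs() >= 1
    }
    out["vsa_don"] = float(heavy_area[sorted(donor_n)].sum()) if donor_n else 0.0
    # typing priority: acidic / basic / donor / acceptor (any N or O) /
    # hydrophobe (C and halogens); whatever matches nothing is "other"
    other = []
    for a in mol.GetAtoms():
        i = a.GetIdx()
        z = a.GetAtomicNum()
        if i in acid_o or i in basic_n or i in donor_n:
            continue
        if z in (7, 8):  # acceptor
            continue
        if z in (6, 9, 17, 35, 53):  # hydrophobe: carbon and halogens
            continue
        other.append(i)
    out["vsa_other"] = float(heavy_area[other].sum()) if other else 0.0

    if panel == "extended":
        out["a_count"] = float(mol_h.GetNumAtoms())
        out["a_heavy"] = float(mol.GetNumAtoms())
        out["a_acc"] = float(rdMolDescriptors.CalcNumHBA(mol))
        out["a_aro"] = float(sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()))
        out["b_rotN"] = float(rdMolDescriptors.CalcNumRotatableBonds(mol))
        out["Weight"] = float(rdMolDescriptors.CalcExactMolWt(mol))

    names = TABLE3_PANEL if panel == "table3" else EXTENDED_PANEL
    return {name: out[name] for name in names}


# --- matrix container and normalization ------------------------------------


@dataclass
class NormalizationParams:
    """Per-column mean/sd learned on training data (population sd)."""

    mean: pd.Series
    sd: pd.Series
    constant: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
            "constant": list(self.constant),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(
            mean=pd.Series(d["mean"]),
            sd=pd.Series(d["sd"]),
            constant=list(d["constant"]),
        )


@dataclass
class DescriptorMatrix:
    """Compounds x named descriptors, with optional stored normalization."""

    values: pd.DataFrame  # index: compound ids; columns: descriptor names
    normalization: NormalizationParams | None = None

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)


def compute_matrix(
    records: list[MoleculeRecord], panel: str = "table3"
) -> DescriptorMatrix:
    """Descriptor matrix for a curated record list (no missing values)."""
    rows = {rec.id: compute_descriptors(rec, panel=panel) for rec in records}
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise DescriptorError(f"missing descriptor values in columns {bad}")
    return DescriptorMatrix(values=df)


def zscore(
    matrix: DescriptorMatrix, params: NormalizationParams | None = None
) -> tuple[DescriptorMatrix, NormalizationParams]:
    """Z-score columns with the population standard deviation.

    With ``params`` given (from training data), applies those parameters
    instead of refitting — external compounds must always be transformed
    with the TRAINING normalization.  Constant columns map to all zeros and
    are flagged.
    """
    df = matrix.values
    if params is None:
        mean = df.mean(axis=0)
        sd = df.std(axis=0, ddof=0)
        constant = sd.index[sd <= 1e-12].tolist()
        params = NormalizationParams(mean=mean, sd=sd, constant=constant)
    sd_safe = params.sd.replace(0.0, 1.0)
    sd_safe[sd_safe <= 1e-12] = 1.0
    z = (df - params.mean) / sd_safe
    z[params.constant] = 0.0
    return DescriptorMatrix(values=z, normalization=params), params


# --- structural keys and similarity ----------------------------------------

N_MACCS_KEYS = 166


@dataclass(frozen=True)
class StructuralKeyFingerprint:
    """166-position structural-key bit vector (the public MACCS set)."""

    bits: frozenset[int]
    n_keys: int = N_MACCS_KEYS

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 1 or max(self.bits) > self.n_keys):
            raise ValueError("bit index outside 1..n_keys")

    def __len__(self) -> int:
        return len(self.bits)


def maccs_keys(record: MoleculeRecord | Chem.Mol) -> StructuralKeyFingerprint:
    """Public 166-key structural fingerprint of a curated record."""
    mol = record.mol if isinstance(record, MoleculeRecord) else record
    fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits; bit 0 unused
    return StructuralKeyFingerprint(bits=frozenset(int(b) for b in fp.GetOnBits()))


def tanimoto(a: StructuralKeyFingerprint, b: StructuralKeyFingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B|; two empty sets are identical (1.0)."""
    if a.n_keys != b.n_keys:
        raise ValueError(f"fingerprint length mismatch: {a.n_keys} vs {b.n_keys}")
    if not a.bits and not b.bits:
        return 1.0
    inter = len(a.bits & b.bits)
    return inter / (len(a.bits) + len(b.bits) - inter)
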