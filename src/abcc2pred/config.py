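"""Pinned chemical vocabularies shared across the pipeline.

Everything that the curation and descriptor layers treat as a convention —
which elements are descriptor-computable, which count as metals, which
substructures are strong acids or bases — lives here as plain data so it can
be inspected, logged and overridden from a config file.
"""

from __future__ import annotations

#: Elements for which every descriptor in the panel is computable.
#: Anything organic outside this set (Se, Te, As, noble gases, ...) is
#: removed during curation.
ALLOWED_ELEMENTS: frozenset[str] = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"}
)

#: Metals in the curation sense: alkali, alkaline-earth, transition,
#: post-transition metals, lanthanides and actinides.
METAL_ELEMENTS: frozenset[str] = frozenset(
    {
        # alkali / alkaline earth
        "Li", "Na", "K", "Rb", "Cs", "Fr",
        "Be", "Mg", "Ca", "Sr", "Ba", "Ra",
        # transition metals
        "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
        "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
        "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
        "Rf", "Db", "Sg", "Bh", "Hs",
        # post-transition
        "Al", "Ga", "In", "Sn", "Tl", "Pb", "Bi", "Po",
        # lanthanides
        "La", "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd", "Tb", "Dy",
        "Ho", "Er", "Tm", "Yb", "Lu",
        # actinides
        "Ac", "Th", "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf",
        "Es", "Fm", "Md", "No", "Lr",
    }
)

# --- Substructure definitions for protonation-state assignment -------------
#
# Strong acids: groups that are essentially fully deprotonated at
# physiological pH.  Each SMARTS marks the acidic hydroxyl oxygen that loses
# the proton (one ionization per match; phosphorus oxyacids ionize once).
STRONG_ACID_SMARTS: dict[str, str] = {
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "sulfonic_acid": "[SX4](=O)(=O)[OX2H1]",
    "sulfinic_acid": "[SX3](=O)[OX2H1]",
    "sulfate_ester": "[OX2][SX4](=O)(=O)[OX2H1]",
    "sulfamate": "[NX3][SX4](=O)(=O)[OX2H1]",
    "phosphonic_acid": "[PX4](=O)[OX2H1]",
}
#: index (within each SMARTS match) of the atom that is deprotonated
STRONG_ACID_SITE_INDEX: dict[str, int] = {
    "carboxylic_acid": 2,
    "sulfonic_acid": 3,
    "sulfinic_acid": 2,
    "sulfate_ester": 3,
    "sulfamate": 3,
    "phosphonic_acid": 2,
}

# Strong bases: nitrogens protonated at physiological pH.  Aliphatic amines
# (primary/secondary/tertiary, not amide/aniline/aromatic), amidines and
# guanidines (protonated on the imine nitrogen).
STRONG_BASE_SMARTS: dict[str, str] = {
    "aliphatic_amine": "[NX3;H2,H1,H0;+0;!$(N-[#6X3]);!$(N-c);!$(N-[!#6;!#1])]",
    "amidine": "[NX2;+0]=[CX3][NX3;+0]",
    "guanidine": "[NX2;+0]=[CX3]([NX3;+0])[NX3;+0]",
}
#: index of the nitrogen that is protonated in each match
STRONG_BASE_SITE_INDEX: dict[str, int] = {
    "aliphatic_amine": 0,
    "amidine": 0,
    "guanidine": 0,
}

#: Name of the tautomer canonicalization rule set applied during
#: standardization; recorded in curation reports for reproducibility.
TAUTOMER_RULESET = "rdkit-MolStandardize-TautomerEnumerator-default"
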