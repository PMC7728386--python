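"""Atom-level chemistry tables: biophysical property rules and van der Waals radii.

Seven boolean property channels are attached to every atom:

``hydrophobic`` aliphatic or aromatic carbons; ``aromatic`` ring carbons of
Phe/Tyr/Trp/His; ``donor`` nitrogen/oxygen/sulfur atoms (lone-pair bearers);
``acceptor`` polar hydrogens (hydrogens bonded to N/O/S); ``positive`` /
``negative`` ionizable-group atoms at physiological pH; ``occupancy`` all
atoms.  The donor/acceptor naming follows the descriptor scheme this package
reproduces, which labels the channels opposite to common hydrogen-bond
convention; ``PropertyRuleSet(swap_donor_acceptor=True)`` swaps them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

CHANNEL_NAMES: tuple[str, ...] = (
    "hydrophobic",
    "aromatic",
    "donor",
    "acceptor",
    "positive",
    "negative",
    "occupancy",
)
N_CHANNELS = len(CHANNEL_NAMES)

AA_3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3: dict[str, str] = {v: k for k, v in AA_3TO1.items()}
STANDARD_AA = frozenset(AA_3TO1)

# Bondi-style radii (Angstrom); overridable through PropertyRuleSet.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}

# Ring carbons per aromatic residue (His counted per the "aromatic carbon" rule).
AROMATIC_RING_CARBONS: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "HIS": frozenset({"CG", "CD2", "CE1"}),
}

# Carbons excluded from the hydrophobic channel: backbone carbonyl C plus
# side-chain carboxyl/amide/guanidinium carbons.
NON_HYDROPHOBIC_SIDECHAIN_C: dict[str, frozenset[str]] = {
    "ASP": frozenset({"CG"}),
    "GLU": frozenset({"CD"}),
    "ASN": frozenset({"CG"}),
    "GLN": frozenset({"CD"}),
    "ARG": frozenset({"CZ"}),
}

# Positively/negatively ionizable atoms at pH 7 (N-terminal amine and
# C-terminal carboxylate handled separately, they are position dependent).
POSITIVE_ATOMS: dict[str, frozenset[str]] = {
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
}
POSITIVE_ATOMS_PROTONATED_HIS: dict[str, frozenset[str]] = {
    **POSITIVE_ATOMS,
    "HIS": frozenset({"ND1", "NE2"}),
}
NEGATIVE_ATOMS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}


@dataclass(frozen=True)
class PropertyRuleSet:
    """Residue/atom-name -> property-flag rules plus the element radius table.

    Parameters
    ----------
    vdw_radii
        Element symbol -> radius in Angstrom.
    default_radius
        Radius assigned to elements absent from the table; ``None`` rejects
        unknown elements with an error.
    swap_donor_acceptor
        Swap the donor and acceptor channels into the conventional
        heavy-atom-donor / hydrogen-free-acceptor assignment.
    protonated_histidine
        Count His imidazole nitrogens as positively ionizable (pH < 6
        conditions); off by default (pH 7).
    """

    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    default_radius: float | None = None
    swap_donor_acceptor: bool = False
    protonated_histidine: bool = False

    def with_overrides(self, **kwargs) -> "PropertyRuleSet":
        return replace(self, **kwargs)

    def radius_for(self, element: str) -> float:
        el = element.strip().upper()
        if el in self.vdw_radii:
            return self.vdw_radii[el]
        if self.default_radius is not None:
            return self.default_radius
        raise KeyError(f"no van der Waals radius for element {element!r}")

    @property
    def positive_atoms(self) -> dict[str, frozenset[str]]:
        if self.protonated_histidine:
            return POSITIVE_ATOMS_PROTONATED_HIS
        return POSITIVE_ATOMS


def hydrogen_parent(h_name: str, heavy_names: list[str]) -> str | None:
    """Resolve the heavy atom a hydrogen is bonded to from PDB naming.

    Standard PDB v3 hydrogen names repeat the remote-position code of their
    parent heavy atom ("HB2" -> "CB", "HD21" -> "ND2", "HH11" -> "NH1").
    The parent is the heavy atom whose name, element letter stripped, is the
    longest prefix of the hydrogen's stripped name.  Bare backbone/terminal
    hydrogens ("H", "H1".."H3") attach to the backbone nitrogen and "HXT" to
    the terminal carboxyl oxygen.
    """
    name = h_name.strip().upper()
    if not name.startswith("H"):
        raise ValueError(f"not a hydrogen atom name: {h_name!r}")
    suffix = name[1:]
    if suffix == "" or suffix.isdigit():
        return "N" if "N" in heavy_names else None
    if name == "HXT":
        return "OXT" if "OXT" in heavy_names else None
    best: str | None = None
    best_len = -1
    for heavy in heavy_names:
        code = heavy.strip().upper()[1:]  # drop the element letter
        if code and suffix.startswith(code) and len(code) > best_len:
            best, best_len = heavy, len(code)
    return best
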