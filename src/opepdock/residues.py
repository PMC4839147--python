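"""Residue-level constants: the 20 standard amino acids, masses, size/stickiness scales.

The canonical residue order used for every 20x20 matrix in this package is
alphabetical by three-letter code (ALA ... VAL).  All matrices, parameter
files and delta maps index residue types through :data:`RESIDUE_TYPES`.
"""

from __future__ import annotations

RESIDUE_TYPES: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

ONE_LETTER: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
THREE_LETTER: dict[str, str] = {v: k for k, v in ONE_LETTER.items()}
TYPE_INDEX: dict[str, int] = {name: i for i, name in enumerate(RESIDUE_TYPES)}

N_TYPES = len(RESIDUE_TYPES)

# Standard atomic masses (u) for heavy atoms occurring in protein side chains.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "SE": 78.971,
}

# Number of heavy side-chain atoms per residue (Gly has none).
HEAVY_SIDECHAIN_ATOMS: dict[str, int] = {
    "ALA": 1, "ARG": 7, "ASN": 4, "ASP": 4, "CYS": 2, "GLN": 5, "GLU": 5,
    "GLY": 0, "HIS": 6, "ILE": 4, "LEU": 4, "LYS": 5, "MET": 4, "PHE": 7,
    "PRO": 3, "SER": 2, "THR": 3, "TRP": 10, "TYR": 8, "VAL": 3,
}

# Effective side-chain bead radius (Angstrom), a smooth function of side-chain
# size used to build the default pair-distance table.
SIDECHAIN_RADIUS: dict[str, float] = {
    "ALA": 2.30, "ARG": 3.20, "ASN": 2.70, "ASP": 2.60, "CYS": 2.50,
    "GLN": 2.90, "GLU": 2.80, "GLY": 2.00, "HIS": 2.90, "ILE": 2.90,
    "LEU": 2.90, "LYS": 3.00, "MET": 2.90, "PHE": 3.10, "PRO": 2.60,
    "SER": 2.40, "THR": 2.60, "TRP": 3.40, "TYR": 3.20, "VAL": 2.70,
}

# Dimensionless "stickiness" scale in [0, 1] driving the default attraction
# magnitudes: aromatic/aliphatic residues high, charged residues low.
STICKINESS: dict[str, float] = {
    "ALA": 0.55, "ARG": 0.20, "ASN": 0.25, "ASP": 0.10, "CYS": 0.70,
    "GLN": 0.25, "GLU": 0.10, "GLY": 0.30, "HIS": 0.40, "ILE": 0.90,
    "LEU": 0.90, "LYS": 0.15, "MET": 0.85, "PHE": 0.95, "PRO": 0.35,
    "SER": 0.30, "THR": 0.35, "TRP": 1.00, "TYR": 0.70, "VAL": 0.80,
}

POSITIVE = frozenset({"ARG", "LYS"})
NEGATIVE = frozenset({"ASP", "GLU"})

#: The four residue-type pairs treated by the salt-bridge potential, keyed by
#: frozenset of three-letter codes.
SALT_BRIDGE_PAIRS: tuple[tuple[str, str], ...] = (
    ("ARG", "ASP"), ("ARG", "GLU"), ("LYS", "ASP"), ("LYS", "GLU"),
)


def salt_bridge_id(res_a: str, res_b: str) -> str | None:
    """Return the canonical salt-bridge pair id (e.g. ``"ARG-ASP"``), or None."""
    for a, b in SALT_BRIDGE_PAIRS:
        if {res_a, res_b} == {a, b}:
            return f"{a}-{b}"
    return None


def is_salt_bridge_pair(i: int, j: int) -> bool:
    return salt_bridge_id(RESIDUE_TYPES[i], RESIDUE_TYPES[j]) is not None
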