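"""All-atom PDB parsing and the six-bead coarse-grained complex model.

Every amino acid is reduced to five backbone beads (N, H, CA, C', O) plus a
single side-chain bead at the mass-weighted centroid of the side-chain heavy
atoms.  Glycine has no side-chain bead; proline keeps one bead per heavy
side-chain atom and has no amide H.  Each residue carries exactly one
*interaction center*: the side-chain bead, or CA for glycine and proline.

A two-partner complex (receptor/ligand, each possibly spanning several
chains) is represented by :class:`CGComplex`, the universal structure object
consumed by the scoring, minimization, evaluation and training modules.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from biotite.structure.io.pdb import PDBFile

from .exceptions import (
    EmptyStructureError,
    MissingAtomError,
    PartnerError,
    PDBParseError,
    UnknownResidueError,
)
from .residues import ATOMIC_MASS, RESIDUE_TYPES, TYPE_INDEX

# Bead role codes (bead_role array values).
ROLE_N = 0
ROLE_H = 1
ROLE_CA = 2
ROLE_CPRIME = 3
ROLE_O = 4
ROLE_SC = 5
ROLE_PRO_HEAVY = 6

ROLE_NAMES = ("N", "H", "CA", "C", "O", "SC", "PH")
#: Roles that belong to the backbone.
BACKBONE_ROLES = frozenset({ROLE_N, ROLE_H, ROLE_CA, ROLE_CPRIME, ROLE_O})

BACKBONE_ATOMS = ("N", "CA", "C", "O")
_NON_SIDECHAIN = {"N", "CA", "C", "O", "OXT"}

GAP_FORCE_CONSTANT = 100.0  # kcal/(mol A^2), applied as E = k (d - d0)^2


@dataclass(frozen=True)
class AtomRecord:
    """One heavy-atom (or amide H) record from a PDB ATOM line."""

    chain_id: str
    residue_seq: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # (3,) Angstrom


@dataclass(frozen=True)
class Bead:
    """A coarse-grained bead (view object; arrays are the computational core)."""

    role: int
    position: np.ndarray
    residue_index: int
    is_interaction_center: bool


@dataclass(frozen=True)
class CGResidue:
    """Per-residue view over the bead arrays."""

    residue_type: int
    beads: tuple[Bead, ...]
    chain_index: int

    @property
    def name(self) -> str:
        return RESIDUE_TYPES[self.residue_type]


@dataclass(frozen=True)
class GapRestraint:
    """Harmonic restraint bridging a numbering gap: E = k (d - d0)^2."""

    bead_a: int  # C' bead before the gap
    bead_b: int  # N bead after the gap
    equilibrium: float  # Angstrom, the distance in the input structure
    force_constant: float = GAP_FORCE_CONSTANT


@dataclass
class CGComplex:
    """Coarse-grained two-partner complex backed by numpy arrays.

    ``chains`` holds residue-index ranges per author chain; ``partner`` maps
    each chain to 0 (receptor), 1 (ligand) or -1 (unassigned).  ``segments``
    lists contiguous residue runs after splitting author chains at numbering
    gaps; scaffold restraints and amide-H reconstruction respect segment
    boundaries.
    """

    bead_pos: np.ndarray        # (n_beads, 3) float64
    bead_role: np.ndarray       # (n_beads,) int8
    bead_residue: np.ndarray    # (n_beads,) int32
    residue_type: np.ndarray    # (n_res,) int8
    residue_chain: np.ndarray   # (n_res,) int16
    center_bead: np.ndarray     # (n_res,) int32 interaction-center bead index
    chain_ids: list[str]
    chains: list[tuple[int, int]]          # residue [start, stop) per chain
    author_seq: np.ndarray      # (n_res,) int32 PDB numbering (metadata only)
    author_icode: list[str]
    partner: np.ndarray = field(default=None)  # (n_chains,) int8
    gap_restraints: list[GapRestraint] = field(default_factory=list)
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.partner is None:
            self.partner = np.full(len(self.chains), -1, dtype=np.int8)
        if not self.segments:
            self.segments = list(self.chains)

    # -- basic sizes ------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return self.bead_pos.shape[0]

    @property
    def n_residues(self) -> int:
        return self.residue_type.shape[0]

    @property
    def partners_assigned(self) -> bool:
        return bool(np.all(self.partner >= 0))

    # -- per-residue / per-bead helpers -----------------------------------
    def residue_partner(self) -> np.ndarray:
        """(n_res,) partner code per residue (-1 if unassigned)."""
        return self.partner[self.residue_chain]

    def bead_partner(self) -> np.ndarray:
        """(n_beads,) partner code per bead."""
        return self.residue_partner()[self.bead_residue]

    def partner_bead_indices(self, which: int) -> np.ndarray:
        return np.nonzero(self.bead_partner() == which)[0]

    def partner_residue_indices(self, which: int) -> np.ndarray:
        return np.nonzero(self.residue_partner() == which)[0]

    def is_center(self) -> np.ndarray:
        mask = np.zeros(self.n_beads, dtype=bool)
        mask[self.center_bead] = True
        return mask

    def residue(self, i: int) -> CGResidue:
        idx = np.nonzero(self.bead_residue == i)[0]
        beads = tuple(
            Bead(int(self.bead_role[b]), self.bead_pos[b].copy(), i,
                 bool(b == self.center_bead[i]))
            for b in idx
        )
        return CGResidue(int(self.residue_type[i]), beads, int(self.residue_chain[i]))

    def residue_bead_indices(self) -> list[np.ndarray]:
        """Bead indices grouped by residue, in residue order."""
        order = np.argsort(self.bead_residue, kind="stable")
        return np.split(order, np.searchsorted(
            self.bead_residue[order], np.arange(1, self.n_residues)))

    # -- transforms --------------------------------------------------------
    def copy(self) -> "CGComplex":
        return replace(
            self,
            bead_pos=self.bead_pos.copy(),
            partner=self.partner.copy(),
            gap_restraints=list(self.gap_restraints),
            segments=list(self.segments),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CGComplex":
        """Rigidly transform all beads: x -> R x + t."""
        out = self.copy()
        out.bead_pos = self.bead_pos @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def with_positions(self, bead_pos: np.ndarray) -> "CGComplex":
        out = self.copy()
        out.bead_pos = np.array(bead_pos, dtype=float)
        return out


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

def _prescan(text: str) -> None:
    """Validate coordinate fields so malformed lines are reported by number."""
    has_atoms = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            has_atoms = True
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fld = line[lo:hi].strip()
                try:
                    val = float(fld)
                except ValueError:
                    raise PDBParseError(
                        f"malformed coordinate field {fld!r} on line {lineno}"
                    ) from None
                if not np.isfinite(val):
                    raise PDBParseError(
                        f"non-finite coordinate on line {lineno}")
    if not has_atoms:
        raise EmptyStructureError("no ATOM records found")


def parse_pdb_models(text: str) -> list[list[AtomRecord]]:
    """Parse PDB text into one :class:`AtomRecord` list per MODEL block.

    HETATM records and waters are dropped; alternate locations are resolved
    by occupancy (ties: first).  Raises :class:`PDBParseError` naming the
    offending line for malformed coordinates and
    :class:`EmptyStructureError` when no protein atoms remain.
    """
    _prescan(text)
    pdb = PDBFile.read(io.StringIO(text))
    n_models = pdb.get_model_count()
    models: list[list[AtomRecord]] = []
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m, altloc="occupancy")
        keep = ~arr.hetero & (arr.res_name != "HOH")
        arr = arr[keep]
        records = [
            AtomRecord(
                chain_id=str(arr.chain_id[k]),
                residue_seq=int(arr.res_id[k]),
                insertion_code=str(arr.ins_code[k]) if hasattr(arr, "ins_code") else "",
                residue_name=str(arr.res_name[k]),
                atom_name=str(arr.atom_name[k]),
                element=str(arr.element[k]),
                position=np.array(arr.coord[k], dtype=float),
            )
            for k in range(arr.array_length())
        ]
        models.append(records)
    if all(len(m) == 0 for m in models):
        raise EmptyStructureError("no protein ATOM records after filtering")
    return models


def parse_pdb(text: str) -> list[AtomRecord]:
    """Parse a single-model PDB text (first model of a multi-model file)."""
    return parse_pdb_models(text)[0]


# ---------------------------------------------------------------------------
# Coarse-graining
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise MissingAtomError("degenerate backbone geometry (zero-length bond)")
    return v / n


def _reconstruct_amide_h(n_pos: np.ndarray, ca_pos: np.ndarray,
                         cprev_pos: np.ndarray | None) -> np.ndarray:
    """Place the amide H 1.0 A from N.

    With a preceding C', H lies on the bisector opposite the N-CA and
    N-C'(prev) bonds; for chain-initial residues it points opposite N-CA.
    Deterministic geometric convention (X-ray inputs carry no hydrogens).
    """
    if cprev_pos is None:
        direction = -_unit(ca_pos - n_pos)
    else:
        direction = -(_unit(ca_pos - n_pos) + _unit(cprev_pos - n_pos))
        nrm = np.linalg.norm(direction)
        if nrm < 1e-8:  # pathological colinear case
            direction = -_unit(ca_pos - n_pos)
        else:
            direction = direction / nrm
    return n_pos + direction


def _sidechain_centroid(atoms: list[AtomRecord]) -> np.ndarray:
    weights = []
    coords = []
    for a in atoms:
        el = a.element.upper() if a.element else a.atom_name[:1].upper()
        weights.append(ATOMIC_MASS.get(el, 12.011))
        coords.append(a.position)
    w = np.asarray(weights)
    return (np.asarray(coords) * w[:, None]).sum(axis=0) / w.sum()


def coarse_grain(atoms: list[AtomRecord]) -> CGComplex:
    """Map all-atom records to the six-bead representation (partners unassigned).

    Backbone beads take their atom positions; the amide H is taken from the
    PDB if present, otherwise reconstructed; the SC bead sits at the
    mass-weighted centroid of side-chain heavy atoms.  Glycine has no SC bead
    (center = CA); proline keeps each heavy side-chain atom as a
    geometry-only bead (center = CA, no H).
    """
    if not atoms:
        raise EmptyStructureError("no atoms to coarse grain")

    # Group atoms by residue in file order.
    groups: list[tuple[tuple[str, int, str], list[AtomRecord]]] = []
    index: dict[tuple[str, int, str], int] = {}
    for a in atoms:
        key = (a.chain_id, a.residue_seq, a.insertion_code)
        if key not in index:
            index[key] = len(groups)
            groups.append((key, []))
        groups[index[key]][1].append(a)

    bead_pos: list[np.ndarray] = []
    bead_role: list[int] = []
    bead_residue: list[int] = []
    residue_type: list[int] = []
    residue_chain: list[int] = []
    center_bead: list[int] = []
    author_seq: list[int] = []
    author_icode: list[str] = []
    chain_ids: list[str] = []
    chains: list[tuple[int, int]] = []

    missing: list[str] = []
    prev_c: np.ndarray | None = None
    prev_chain: str | None = None
    chain_start = 0

    for ri, ((chain_id, seq, icode), res_atoms) in enumerate(groups):
        res_name = res_atoms[0].residue_name
        if res_name not in TYPE_INDEX:
            raise UnknownResidueError(
                f"residue {res_name} {chain_id}{seq} is not a standard amino acid")
        if chain_id != prev_chain:
            if prev_chain is not None:
                chains.append((chain_start, ri))
                chain_ids.append(prev_chain)
            chain_start = ri
            prev_chain = chain_id
            prev_c = None

        by_name = {a.atom_name: a for a in res_atoms}
        absent = [nm for nm in BACKBONE_ATOMS if nm not in by_name]
        if absent:
            missing.append(f"{res_name} {chain_id}{seq}: missing {','.join(absent)}")
            continue

        n_pos = by_name["N"].position
        ca_pos = by_name["CA"].position
        c_pos = by_name["C"].position
        o_pos = by_name["O"].position

        bead_pos.append(n_pos); bead_role.append(ROLE_N); bead_residue.append(ri)
        if res_name != "PRO":
            h_atom = by_name.get("H") or by_name.get("HN") or by_name.get("H1")
            h_pos = h_atom.position if h_atom is not None else \
                _reconstruct_amide_h(n_pos, ca_pos, prev_c)
            bead_pos.append(h_pos); bead_role.append(ROLE_H); bead_residue.append(ri)
        bead_pos.append(ca_pos); bead_role.append(ROLE_CA); bead_residue.append(ri)
        ca_index = len(bead_pos) - 1
        bead_pos.append(c_pos); bead_role.append(ROLE_CPRIME); bead_residue.append(ri)
        bead_pos.append(o_pos); bead_role.append(ROLE_O); bead_residue.append(ri)

        sc_atoms = [a for a in res_atoms
                    if a.atom_name not in _NON_SIDECHAIN
                    and not a.atom_name.startswith("H")
                    and a.atom_name not in ("H", "HN", "H1")]
        if res_name == "GLY":
            center_bead.append(ca_index)
        elif res_name == "PRO":
            for a in sc_atoms:
                bead_pos.append(a.position)
                bead_role.append(ROLE_PRO_HEAVY)
                bead_residue.append(ri)
            center_bead.append(ca_index)
        else:
            if not sc_atoms:
                # An error is raised below; no need to roll back bead buffers.
                missing.append(f"{res_name} {chain_id}{seq}: missing side-chain atoms")
                continue
            bead_pos.append(_sidechain_centroid(sc_atoms))
            bead_role.append(ROLE_SC)
            bead_residue.append(ri)
            center_bead.append(len(bead_pos) - 1)

        residue_type.append(TYPE_INDEX[res_name])
        residue_chain.append(len(chain_ids))
        author_seq.append(seq)
        author_icode.append(icode)
        prev_c = c_pos

    if missing:
        raise MissingAtomError("incomplete residues: " + "; ".join(missing))
    chains.append((chain_start, len(groups)))
    chain_ids.append(prev_chain)

    # Residue indices were assigned per input group; compact them (all groups
    # survived or an error was raised, so they are already contiguous).
    return CGComplex(
        bead_pos=np.asarray(bead_pos, dtype=float),
        bead_role=np.asarray(bead_role, dtype=np.int8),
        bead_residue=np.asarray(bead_residue, dtype=np.int32),
        residue_type=np.asarray(residue_type, dtype=np.int8),
        residue_chain=np.asarray(residue_chain, dtype=np.int16),
        center_bead=np.asarray(center_bead, dtype=np.int32),
        chain_ids=chain_ids,
        chains=chains,
        author_seq=np.asarray(author_seq, dtype=np.int32),
        author_icode=author_icode,
    )


def assign_partners(complex: CGComplex, receptor_chains: set[str],
                    ligand_chains: set[str]) -> CGComplex:
    """Label author chains as receptor or ligand (explicit, never inferred).

    All chains from one binding partner are treated as a single protein.
    """
    receptor_chains = set(receptor_chains)
    ligand_chains = set(ligand_chains)
    overlap = receptor_chains & ligand_chains
    if overlap:
        raise PartnerError(f"chains assigned to both partners: {sorted(overlap)}")
    known = set(complex.chain_ids)
    unknown = (receptor_chains | ligand_chains) - known
    if unknown:
        raise PartnerError(f"unknown chain ids: {sorted(unknown)}")
    uncovered = known - (receptor_chains | ligand_chains)
    if uncovered:
        raise PartnerError(f"chains not assigned to a partner: {sorted(uncovered)}")
    out = complex.copy()
    out.partner = np.array(
        [0 if cid in receptor_chains else 1 for cid in complex.chain_ids],
        dtype=np.int8)
    for which, name in ((0, "receptor"), (1, "ligand")):
        if not np.any(out.residue_partner() == which):
            raise PartnerError(f"{name} has no residues")
    return out


def detect_chain_gaps(complex: CGComplex) -> list[GapRestraint]:
    """Find numbering discontinuities within author chains.

    Each gap yields a harmonic C'->N restraint with the current distance as
    equilibrium and k = 100 kcal/(mol A^2); the chain is split into segments
    at the gap (recorded in ``complex.segments``).  Insertion codes count as
    sequential residues; inter-chain boundaries are not gaps.
    """
    restraints: list[GapRestraint] = []
    segments: list[tuple[int, int]] = []
    role = complex.bead_role
    resid = complex.bead_residue

    def bead_of(res: int, want: int) -> int:
        idx = np.nonzero((resid == res) & (role == want))[0]
        return int(idx[0])

    for ci, (start, stop) in enumerate(complex.chains):
        seg_start = start
        for r in range(start + 1, stop):
            step = int(complex.author_seq[r]) - int(complex.author_seq[r - 1])
            icode_change = complex.author_icode[r] != complex.author_icode[r - 1]
            contiguous = step == 1 or (step == 0 and icode_change)
            if not contiguous:
                a = bead_of(r - 1, ROLE_CPRIME)
                b = bead_of(r, ROLE_N)
                d0 = float(np.linalg.norm(complex.bead_pos[a] - complex.bead_pos[b]))
                restraints.append(GapRestraint(a, b, d0))
                segments.append((seg_start, r))
                seg_start = r
        segments.append((seg_start, stop))
    complex.gap_restraints = restraints
    complex.segments = segments
    return restraints


# ---------------------------------------------------------------------------
# CG-PDB dialect and topology I/O
# ---------------------------------------------------------------------------

def write_cg_pdb(complex: CGComplex, model_sets: list[np.ndarray] | None = None) -> str:
    """Serialize bead positions as a PDB dialect (one ATOM per bead).

    The bead role is written in the atom-name field.  ``model_sets`` allows
    writing several position sets (decoys) as MODEL blocks sharing the
    topology.
    """
    sets = model_sets if model_sets is not None else [complex.bead_pos]
    multi = len(sets) > 1
    lines: list[str] = []
    for mi, pos in enumerate(sets, start=1):
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        serial = 1
        for b in range(complex.n_beads):
            ri = int(complex.bead_residue[b])
            name = ROLE_NAMES[complex.bead_role[b]]
            res = RESIDUE_TYPES[complex.residue_type[ri]]
            chain = complex.chain_ids[complex.residue_chain[ri]][:1] or "A"
            seq = int(complex.author_seq[ri])
            x, y, z = pos[b]
            name_field = name if len(name) == 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name_field:4s} {res:3s} {chain}{seq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}")
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_cg_pdb_positions(text: str) -> list[np.ndarray]:
    """Read back position sets written by :func:`write_cg_pdb`."""
    sets: list[list[list[float]]] = []
    current: list[list[float]] = []
    saw_model = False
    for line in text.splitlines():
        if line.startswith("MODEL"):
            saw_model = True
            current = []
        elif line.startswith("ENDMDL"):
            sets.append(current)
        elif line.startswith("ATOM"):
            current.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    if not saw_model:
        sets = [current]
    return [np.asarray(s, dtype=float) for s in sets]


def write_topology(complex: CGComplex) -> str:
    """Structured key/value topology text (chains, partners, gaps)."""
    lines = ["# opepdock topology v1"]
    lines.append(f"n_residues {complex.n_residues}")
    lines.append(f"n_beads {complex.n_beads}")
    for ci, (start, stop) in enumerate(complex.chains):
        part = {0: "receptor", 1: "ligand", -1: "unassigned"}[int(complex.partner[ci])]
        lines.append(f"chain {complex.chain_ids[ci]} residues {start} {stop} partner {part}")
    for g in complex.gap_restraints:
        lines.append(
            f"gap {g.bead_a} {g.bead_b} equilibrium {g.equilibrium:.6f} "
            f"k {g.force_constant:.1f}")
    return "\n".join(lines) + "\n"
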