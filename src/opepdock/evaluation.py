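"""Interface RMSD, hit ranking, success rates and accuracy classes.

The interface of the reference (co-crystallized) complex is the set of
residues with any bead within 10 A of the partner; IRMSD is the RMSD over
the interface CA beads after optimal least-squares rigid superposition
(proper rotation, det = +1).  A *hit* is a decoy with IRMSD strictly below
4 A.  Decoys are ranked by ascending score; the success rate over a target
set is the fraction of targets with a hit among the top-N ranked decoys.
Accuracy classes follow the IRMSD-only reading of the CAPRI tiers:
high <= 1 A, medium <= 2 A, acceptable < 4 A, else incorrect.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .cgmodel import CGComplex, ROLE_CA
from .exceptions import GeometryError, OpepdockError, PartnerError

HIT_IRMSD = 4.0  # Angstrom, strict upper bound
INTERFACE_CUTOFF = 10.0  # Angstrom
RANK_CAP = 2000  # substitution value for targets without a hit


@dataclass
class DecoySet:
    """A reference complex plus rigid-body decoy poses of its ligand.

    Decoys share the reference topology; only the ligand bead positions
    vary.  ``transforms`` optionally stores the rigid motion (rotation
    matrix, translation) that generated each pose from the native ligand.
    """

    reference: CGComplex
    decoy_ids: list[str]
    ligand_positions: np.ndarray      # (n_decoys, n_ligand_beads, 3)
    target_id: str = "target"
    complex_class: str = "other"      # enzyme_inhibitor | antigen_antibody | other
    irmsd: np.ndarray | None = None
    scores: np.ndarray | None = None
    near_native: np.ndarray | None = None
    transforms: list | None = None

    def __post_init__(self) -> None:
        if len(set(self.decoy_ids)) != len(self.decoy_ids):
            raise OpepdockError("decoy ids must be unique")
        if self.complex_class not in ("enzyme_inhibitor", "antigen_antibody", "other"):
            raise OpepdockError(f"unknown complex class {self.complex_class!r}")

    @property
    def n_decoys(self) -> int:
        return len(self.decoy_ids)

    def ligand_bead_indices(self) -> np.ndarray:
        return self.reference.partner_bead_indices(1)

    def decoy_complex(self, i: int) -> CGComplex:
        """Full CGComplex for decoy ``i`` (receptor fixed, ligand posed)."""
        out = self.reference.copy()
        out.bead_pos[self.ligand_bead_indices()] = self.ligand_positions[i]
        return out


# ---------------------------------------------------------------------------
# IRMSD
# ---------------------------------------------------------------------------

def interface_selection(reference: CGComplex,
                        cutoff: float = INTERFACE_CUTOFF) -> np.ndarray:
    """CA bead indices of interface residues of the reference complex.

    A residue is interfacial iff any of its beads lies within ``cutoff`` of
    any bead of the other partner (strictly below).  Decoys inherit this
    selection; it is never recomputed on a decoy.
    """
    if not reference.partners_assigned:
        raise PartnerError("assign partners before selecting the interface")
    rec = reference.partner_bead_indices(0)
    lig = reference.partner_bead_indices(1)
    tree = cKDTree(reference.bead_pos[lig])
    d_rec, _ = tree.query(reference.bead_pos[rec])
    tree_r = cKDTree(reference.bead_pos[rec])
    d_lig, _ = tree_r.query(reference.bead_pos[lig])

    res_partner = reference.residue_partner()
    interfacial = np.zeros(reference.n_residues, dtype=bool)
    for beads, dists in ((rec, d_rec), (lig, d_lig)):
        close = beads[dists < cutoff]
        interfacial[np.unique(reference.bead_residue[close])] = True

    ca = np.nonzero(reference.bead_role == ROLE_CA)[0]
    ca_of_res = {int(reference.bead_residue[b]): int(b) for b in ca}
    sel = np.array([ca_of_res[r] for r in np.nonzero(interfacial)[0]], dtype=int)
    if sel.size == 0:
        raise GeometryError("empty interface: partners are not in contact "
                            "in the reference complex")
    return sel


def superpose_rmsd(reference_xyz: np.ndarray, mobile_xyz: np.ndarray) -> float:
    """RMSD after optimal proper-rotation superposition (Kabsch)."""
    ref = np.asarray(reference_xyz, dtype=float)
    mob = np.asarray(mobile_xyz, dtype=float)
    if ref.shape != mob.shape or ref.shape[0] < 3:
        raise GeometryError("need >= 3 matched points for superposition")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    return float(rssd / np.sqrt(ref.shape[0]))


def compute_irmsd(reference: CGComplex, decoy_positions: np.ndarray,
                  interface_ca: np.ndarray) -> float:
    """IRMSD of a decoy: superpose its interface CAs onto the reference's.

    ``decoy_positions`` is the decoy's full bead-position array (same
    topology as the reference).
    """
    return superpose_rmsd(reference.bead_pos[interface_ca],
                          np.asarray(decoy_positions)[interface_ca])


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def rank_and_best_hit(decoy_ids, scores, irmsds) -> tuple[pd.DataFrame, int | None]:
    """Rank decoys by ascending score (ties: ascending decoy id).

    Returns the ranking table (rank, decoy_id, score, irmsd, hit, class)
    and the best-hit rank (smallest rank with IRMSD < 4 A), or None.
    """
    scores = np.asarray(scores, dtype=float)
    if np.any(np.isnan(scores)):
        bad = np.asarray(decoy_ids)[np.isnan(scores)]
        raise OpepdockError(f"NaN score for decoy {bad[0]!r}")
    df = pd.DataFrame({"decoy_id": list(decoy_ids), "score": scores,
                       "irmsd": np.asarray(irmsds, dtype=float)})
    df = df.sort_values(["score", "decoy_id"], kind="stable").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df["hit"] = df["irmsd"] < HIT_IRMSD
    df["accuracy"] = [accuracy_class(v) for v in df["irmsd"]]
    hits = df.index[df["hit"]]
    best = int(df.loc[hits[0], "rank"]) if len(hits) else None
    return df, best


def success_rate(best_hit_ranks, n_max: int | None = None) -> pd.DataFrame:
    """Success curve S(N) = fraction of targets with a hit at rank <= N."""
    ranks = list(best_hit_ranks)
    if not ranks:
        raise OpepdockError("success rate needs at least one target")
    if n_max is None:
        finite = [r for r in ranks if r is not None]
        n_max = max(finite) if finite else 1
    n_pred = np.arange(1, n_max + 1)
    rate = np.array([
        sum(1 for r in ranks if r is not None and r <= n) / len(ranks)
        for n in n_pred
    ])
    return pd.DataFrame({"n_pred": n_pred, "success_rate": rate})


def accuracy_class(irmsd: float) -> str:
    """IRMSD-only accuracy tier: <=1 high, <=2 medium, <4 acceptable."""
    if irmsd < 0:
        raise OpepdockError("IRMSD cannot be negative")
    if irmsd <= 1.0:
        return "high"
    if irmsd <= 2.0:
        return "medium"
    if irmsd < HIT_IRMSD:
        return "acceptable"
    return "incorrect"


def summarize_mean_rank(best_hit_ranks, policy: str = "exclude_missing") -> float:
    """Class-average best-hit rank under one of two no-hit policies.

    ``substitute_2000`` replaces missing ranks by 2000 before averaging;
    ``exclude_missing`` drops targets without a hit.  The result is rounded
    half-up to one decimal, the precision of published benchmark tables.
    """
    ranks = list(best_hit_ranks)
    if not ranks:
        raise OpepdockError("no targets")
    if policy == "substitute_2000":
        vals = [RANK_CAP if r is None else r for r in ranks]
    elif policy == "exclude_missing":
        vals = [r for r in ranks if r is not None]
        if not vals:
            raise OpepdockError("all targets lack hits under exclude_missing")
    else:
        raise OpepdockError(f"unknown policy {policy!r}")
    mean = Decimal(sum(vals)) / Decimal(len(vals))
    return float(mean.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def irmsd_change_profile(irmsd_before, irmsd_after) -> pd.DataFrame:
    """Binned mean +/- sd of the minimization-induced IRMSD change.

    Bins of 1 A on the initial IRMSD; also reports the fraction of decoys
    whose IRMSD decreased.
    """
    before = np.asarray(irmsd_before, dtype=float)
    after = np.asarray(irmsd_after, dtype=float)
    delta = after - before
    df = pd.DataFrame({"bin": np.floor(before).astype(int), "delta": delta})
    out = df.groupby("bin")["delta"].agg(["mean", "std", "count"])
    out["fraction_decreased"] = df.groupby("bin")["delta"].apply(
        lambda s: float(np.mean(s < 0)))
    return out
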