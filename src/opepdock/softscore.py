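"""The softened 8-6 rescoring energy E_86 with per-term decomposition.

The side chain - side chain attraction and the backbone 12-6 van der Waals
term are replaced by 8-6 Lennard-Jones curves,

    E_86term(r) = eps' [ (sigma'/r)^8 - (sigma'/r)^6 ],

constructed so the minimum of each softened curve coincides in position and
depth with the curve it replaces.  The 8-6 family fixes both conversion
constants analytically: the minimum sits at r_min = sigma' sqrt(4/3), i.e.
sigma'/r_min = sqrt(3)/2 = 0.866, and the well depth is
-eps' (0.75^3 - 0.75^4) = -eps'/9.481.  Hence sigma' = 0.866 sigma and
eps' = 9.481 |E_SS(sigma)|.  The broader 8-6 well tolerates bead overlap and
keeps imperfectly fitted contacts attractive at larger distances.  The
repulsive-only branch, the H-bond term and the salt-bridge profiles are not
modified:

    E_86 = E_VDW86 + E_SS86 + E_HB + E_SB

summed over bead pairs with one bead in each binding partner only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cgmodel import (
    BACKBONE_ROLES,
    CGComplex,
    ROLE_CPRIME,
    ROLE_H,
    ROLE_N,
    ROLE_O,
    ROLE_PRO_HEAVY,
)
from .exceptions import ParameterError, PartnerError
from .forcefield import (
    ForceFieldConfig,
    PairParameterTable,
    combine_vdw,
    ess_pair,
)
from .residues import N_TYPES, RESIDUE_TYPES, is_salt_bridge_pair

#: sigma'/sigma for the 8-6 construction (exact value of the printed 0.866).
SOFT_SIGMA_RATIO = float(np.sqrt(3.0) / 2.0)
#: |eps'| / |E_SS(sigma)| (exact value of the printed 9.481).
SOFT_DEPTH_RATIO = 1.0 / (0.75 ** 3 - 0.75 ** 4)


@dataclass
class SoftPairTable:
    """8-6 parameters derived from a :class:`PairParameterTable`.

    Attractive entries carry sigma' = 0.866 sigma and eps' = 9.481 eps
    (eps = |E_SS(sigma)| for the 12-6 well); repulsive entries are copied
    unmodified and keep delegating to the unsoftened repulsive branch.
    """

    sigma_prime: np.ndarray   # (20, 20) Angstrom (= sigma for repulsive entries)
    eps_prime: np.ndarray     # (20, 20) kcal/mol, magnitudes
    attractive: np.ndarray    # (20, 20) bool (copied flags)
    base_table: PairParameterTable
    vdw_soft: dict[tuple[int, int], tuple[float, float]]  # role pair -> (sigma', eps')

    def well_depth(self, i: int, j: int) -> float:
        """Minimum energy of the (i, j) entry: -eps for attractive pairs,
        the value at sigma (+eps) for repulsive-only pairs."""
        if self.attractive[i, j]:
            return -float(self.eps_prime[i, j] / SOFT_DEPTH_RATIO)
        return float(self.base_table.eps[i, j])


@dataclass
class EnergyBreakdown:
    """E_86 decomposed into its four inter-partner terms (kcal/mol)."""

    e_vdw86: float
    e_ss86: float
    e_hb: float
    e_sb: float
    n_pairs_evaluated: int

    @property
    def total(self) -> float:
        return self.e_vdw86 + self.e_ss86 + self.e_hb + self.e_sb


def soften_parameters(table: PairParameterTable,
                      config: ForceFieldConfig | None = None) -> SoftPairTable:
    """Derive the 8-6 tables from the 12-6/E_SS parameters.

    The identical construction is applied to the van der Waals role pairs
    (E_VDW86): minimum position and depth of each 12-6 curve are preserved.
    """
    sigma_prime = np.where(table.attractive,
                           SOFT_SIGMA_RATIO * table.sigma, table.sigma)
    eps_prime = np.where(table.attractive,
                         SOFT_DEPTH_RATIO * table.eps, table.eps)
    vdw = (config.vdw if config is not None else None)
    vdw_soft: dict[tuple[int, int], tuple[float, float]] = {}
    if vdw is not None:
        for a in vdw:
            for b in vdw:
                radius, depth = combine_vdw(a, b, vdw)
                vdw_soft[(a, b)] = (SOFT_SIGMA_RATIO * radius,
                                    SOFT_DEPTH_RATIO * depth)
    return SoftPairTable(sigma_prime=sigma_prime, eps_prime=eps_prime,
                         attractive=table.attractive.copy(),
                         base_table=table, vdw_soft=vdw_soft)


def _e86(r, sigma_prime, eps_prime):
    x = sigma_prime / r
    x6 = x ** 6
    return eps_prime * (x6 * x ** 2 - x6)


def _e86_derivative(r, sigma_prime, eps_prime):
    x = sigma_prime / r
    x6 = x ** 6
    return eps_prime * (-8.0 * x6 * x ** 2 + 6.0 * x6) / r


def ess86_pair(r, i: int, j: int, soft: SoftPairTable):
    """Softened side chain - side chain energy E_SS86(r).

    Attractive: the 8-6 form with (sigma', eps'); repulsive: delegates to
    the unsoftened repulsive branch of E_SS.
    """
    if is_salt_bridge_pair(i, j):
        raise ParameterError("salt-bridge pairs route to the E_SB profile")
    r = np.asarray(r, dtype=float)
    if soft.attractive[i, j]:
        out = _e86(r, soft.sigma_prime[i, j], soft.eps_prime[i, j])
        return float(out) if out.ndim == 0 else out
    return ess_pair(r, i, j, soft.base_table)


def evdw86_pair(r, role_a: int, role_b: int, soft: SoftPairTable):
    """Softened backbone van der Waals energy E_VDW86(r)."""
    key = (role_a, role_b) if (role_a, role_b) in soft.vdw_soft else (role_b, role_a)
    sigma_prime, eps_prime = soft.vdw_soft[key]
    out = _e86(np.asarray(r, dtype=float), sigma_prime, eps_prime)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Complex scoring
# ---------------------------------------------------------------------------

def _inter_partner_pairs(complex: CGComplex, cutoff: float | None):
    """Index pairs (receptor bead, ligand bead) within the cutoff."""
    rec = complex.partner_bead_indices(0)
    lig = complex.partner_bead_indices(1)
    if cutoff is None:
        ii, jj = np.meshgrid(rec, lig, indexing="ij")
        return ii.ravel(), jj.ravel()
    tree_r = cKDTree(complex.bead_pos[rec])
    tree_l = cKDTree(complex.bead_pos[lig])
    pairs = tree_r.query_ball_tree(tree_l, cutoff)
    ii = np.concatenate([[ri] * len(p) for ri, p in zip(rec, pairs)]) \
        if any(pairs) else np.empty(0, dtype=int)
    jj = np.concatenate([lig[p] for p in pairs if p]) \
        if any(pairs) else np.empty(0, dtype=int)
    return ii.astype(int), jj.astype(int)


def score_e86(complex: CGComplex, soft: SoftPairTable,
              config: ForceFieldConfig) -> EnergyBreakdown:
    """Compute E_86 = E_VDW86 + E_SS86 + E_HB + E_SB between the partners.

    Pair routing: interaction-center/interaction-center pairs go to E_SS86
    (or E_SB for the four salt-bridge type pairs); every other pair with at
    least one backbone bead (N, CA, C', O) goes to E_VDW86; H beads enter
    only E_HB; proline heavy-atom beads are geometry-only.  With a finite
    cutoff every radial term is shifted to zero at the cutoff.
    Intra-partner pairs contribute nothing.
    """
    if not complex.partners_assigned:
        raise PartnerError("assign receptor/ligand chains before scoring")
    cutoff = config.cutoff
    ii, jj = _inter_partner_pairs(complex, cutoff)
    n_pairs = int(len(ii))
    if n_pairs == 0:
        return EnergyBreakdown(0.0, 0.0, _score_hb(complex, config), 0.0, 0)

    d = np.linalg.norm(complex.bead_pos[ii] - complex.bead_pos[jj], axis=1)
    role_i = complex.bead_role[ii]
    role_j = complex.bead_role[jj]
    center = complex.is_center()
    cc = center[ii] & center[jj]

    ti = complex.residue_type[complex.bead_residue[ii]]
    tj = complex.residue_type[complex.bead_residue[jj]]
    per_type = score_ss_sb_by_type(d[cc], ti[cc], tj[cc], soft, config)
    e_ss86 = float(per_type["ss86"].sum())
    e_sb = float(per_type["sb"].sum())

    # --- E_VDW86 over backbone-involving, non-center-center pairs -------
    bb = (np.isin(role_i, list(BACKBONE_ROLES)) |
          np.isin(role_j, list(BACKBONE_ROLES)))
    ok = (bb & ~cc & (role_i != ROLE_H) & (role_j != ROLE_H)
          & (role_i != ROLE_PRO_HEAVY) & (role_j != ROLE_PRO_HEAVY))
    e_vdw86 = 0.0
    if np.any(ok):
        sig, eps = _vdw_soft_lookup(soft)
        sp = sig[role_i[ok], role_j[ok]]
        ep = eps[role_i[ok], role_j[ok]]
        e = _e86(d[ok], sp, ep)
        if cutoff is not None:
            e = e - _e86(cutoff, sp, ep)
        e_vdw86 = float(e.sum())

    e_hb = _score_hb(complex, config)
    return EnergyBreakdown(e_vdw86=float(e_vdw86), e_ss86=float(e_ss86),
                           e_hb=float(e_hb), e_sb=float(e_sb),
                           n_pairs_evaluated=n_pairs)


def _sb_type_mask() -> np.ndarray:
    mask = np.zeros((N_TYPES, N_TYPES), dtype=bool)
    for a in range(N_TYPES):
        for b in range(N_TYPES):
            mask[a, b] = is_salt_bridge_pair(a, b)
    return mask


_SB_MASK = _sb_type_mask()


def _vdw_soft_lookup(soft: SoftPairTable) -> tuple[np.ndarray, np.ndarray]:
    """Dense (role x role) sigma'/eps' lookup tables for E_VDW86."""
    cached = getattr(soft, "_vdw_lookup", None)
    if cached is not None:
        return cached
    n_roles = 7
    sig = np.full((n_roles, n_roles), np.nan)
    eps = np.full((n_roles, n_roles), np.nan)
    for (a, b), (sp, ep) in soft.vdw_soft.items():
        sig[a, b] = sig[b, a] = sp
        eps[a, b] = eps[b, a] = ep
    soft._vdw_lookup = (sig, eps)
    return sig, eps


def score_ss_sb_by_type(d: np.ndarray, ti: np.ndarray, tj: np.ndarray,
                        soft: SoftPairTable, config: ForceFieldConfig,
                        scale: np.ndarray | None = None) -> dict:
    """Vectorized E_SS86/E_SB over interaction-center pairs.

    ``d`` are center-center distances with residue types ``ti``/``tj``.
    ``scale`` optionally multiplies each pair's energy by a per-type-pair
    factor (20x20), which is how trained well depths re-enter scoring.
    Returns per-pair energy arrays under keys ``"ss86"`` and ``"sb"``.
    """
    cutoff = config.cutoff
    d = np.asarray(d, dtype=float)
    ti = np.asarray(ti, dtype=int)
    tj = np.asarray(tj, dtype=int)
    ss = np.zeros(d.shape)
    sb = np.zeros(d.shape)
    if d.size == 0:
        return {"ss86": ss, "sb": sb}
    fac = np.ones(d.shape) if scale is None else scale[ti, tj]

    is_sb = _SB_MASK[ti, tj]
    att = soft.attractive[ti, tj] & ~is_sb
    rep = ~soft.attractive[ti, tj] & ~is_sb

    if np.any(att):
        sp = soft.sigma_prime[ti[att], tj[att]]
        ep = soft.eps_prime[ti[att], tj[att]]
        e = _e86(d[att], sp, ep)
        if cutoff is not None:
            e = e - _e86(cutoff, sp, ep)
        ss[att] = e * fac[att]
    if np.any(rep):
        base = soft.base_table
        sg = base.sigma[ti[rep], tj[rep]]
        ep = base.eps[ti[rep], tj[rep]]
        e = ep * (sg / d[rep]) ** 6
        if cutoff is not None:
            e = e - ep * (sg / cutoff) ** 6
        ss[rep] = e * fac[rep]
    if np.any(is_sb):
        names = [RESIDUE_TYPES[a] for a in range(N_TYPES)]
        for pid, prof in config.sb_profiles.items():
            na, nb = pid.split("-")
            a, b = names.index(na), names.index(nb)
            m = is_sb & (((ti == a) & (tj == b)) | ((ti == b) & (tj == a)))
            if np.any(m):
                e = prof(d[m])
                if cutoff is not None and cutoff < prof.distance_grid[-1]:
                    e = e - prof(cutoff)
                sb[m] = e * fac[m]
    return {"ss86": ss, "sb": sb}


def _score_hb(complex: CGComplex, config: ForceFieldConfig) -> float:
    """Inter-partner backbone H-bond sum (donor N-H of one partner against
    acceptor C'=O of the other, both directions)."""
    from .forcefield import ehb_pair  # local import to avoid cycle at module load

    params = config.hb
    pos = complex.bead_pos
    role = complex.bead_role
    resid = complex.bead_residue
    rp = complex.residue_partner()

    def donors(which):
        out = []
        h_idx = np.nonzero((role == ROLE_H) &
                           (rp[resid] == which))[0]
        for h in h_idx:
            r = resid[h]
            n = np.nonzero((resid == r) & (role == ROLE_N))[0][0]
            out.append((int(n), int(h)))
        return out

    def acceptors(which):
        out = []
        o_idx = np.nonzero((role == ROLE_O) & (rp[resid] == which))[0]
        for o in o_idx:
            r = resid[o]
            c = np.nonzero((resid == r) & (role == ROLE_CPRIME))[0][0]
            out.append((int(c), int(o)))
        return out

    total = 0.0
    for don_side, acc_side in ((0, 1), (1, 0)):
        accs = acceptors(acc_side)
        if not accs:
            continue
        o_positions = np.asarray([pos[o] for _, o in accs])
        for n, h in donors(don_side):
            dists = np.linalg.norm(o_positions - pos[h], axis=1)
            for k in np.nonzero(dists <= params.cutoff)[0]:
                c, o = accs[k]
                total += ehb_pair(pos[n], pos[h], pos[c], pos[o], None, params)
    return float(total)


# ---------------------------------------------------------------------------
# Energy-vs-IRMSD binning
# ---------------------------------------------------------------------------

def bin_energies_by_irmsd(irmsd, breakdowns) -> "pd.DataFrame":
    """Mean and standard deviation of E_SS86, E_SB, E_HB in 1 A IRMSD bins.

    Bins are [k, k+1); empty bins are absent from the output (flagged by
    omission, never zero-filled).
    """
    import pandas as pd

    rows = []
    for r, b in zip(irmsd, breakdowns):
        rows.append({"irmsd": float(r), "e_ss86": b.e_ss86, "e_sb": b.e_sb,
                     "e_hb": b.e_hb})
    df = pd.DataFrame(rows)
    df["bin"] = np.floor(df["irmsd"]).astype(int)
    grouped = df.groupby("bin")[["e_ss86", "e_sb", "e_hb"]]
    out = grouped.agg(["mean", "std", "count"])
    out.columns = ["_".join(c) for c in out.columns]
    return out
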