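"""Restrained Cartesian energy minimization of coarse-grained decoys.

Decoys arriving from a grid-based rigid-body search carry bead clashes after
coarse-graining; a short relaxation (default 140 limited-memory BFGS steps)
removes them before rescoring.  Covalent geometry is preserved by a
*self-consistent harmonic scaffold*: bond, 1-3 (angle) and side-chain tether
restraints whose equilibria are read off the input conformation, so the
restraint energy of the input is exactly zero and only the nonbonded terms
(plus any chain-gap restraints) drive the relaxation.  All harmonic terms
use E = k (d - d0)^2 without the 1/2 factor, so a printed force constant of
100 kcal/(mol A^2) applies literally.

The relaxation energy comprises the scaffold, the gap restraints and the
unsoftened nonbonded terms (E_VDW 12-6, E_SS, E_SB) over intra- and
inter-partner bead pairs; the orientation-dependent H-bond term is scoring
only and is excluded from the relaxation gradient.  Both partners relax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as scipy_minimize

from .cgmodel import (
    CGComplex,
    ROLE_CA,
    ROLE_CPRIME,
    ROLE_H,
    ROLE_N,
    ROLE_O,
    ROLE_PRO_HEAVY,
    ROLE_SC,
)
from .exceptions import MinimizationError
from .forcefield import ForceFieldConfig, damping_length
from .softscore import _SB_MASK

DEFAULT_STEPS = 140

#: Default scaffold stiffnesses, kcal/(mol A^2).
STIFFNESS = {"bond": 100.0, "angle": 40.0, "tether": 20.0, "torsion": 20.0}


@dataclass
class RestraintSet:
    """Harmonic pair restraints E = k (d - d0)^2 over bead index pairs."""

    idx_a: np.ndarray
    idx_b: np.ndarray
    equilibrium: np.ndarray
    force_constant: np.ndarray

    @property
    def n(self) -> int:
        return len(self.idx_a)

    def energy(self, pos: np.ndarray) -> float:
        d = np.linalg.norm(pos[self.idx_a] - pos[self.idx_b], axis=1)
        return float(np.sum(self.force_constant * (d - self.equilibrium) ** 2))


@dataclass
class MinimizationResult:
    positions: np.ndarray
    energy_trace: np.ndarray  # energy at the input plus each accepted step
    n_steps_taken: int
    converged: bool


def _bead_lookup(complex: CGComplex) -> dict[tuple[int, int], int]:
    table: dict[tuple[int, int], int] = {}
    for b in range(complex.n_beads):
        table[(int(complex.bead_residue[b]), int(complex.bead_role[b]))] = b
    return table


def build_scaffold_restraints(complex: CGComplex,
                              stiffness: dict[str, float] | None = None
                              ) -> RestraintSet:
    """Harmonic scaffold with equilibria taken from the input conformation.

    Restraints: intra-residue bonds (N-H, N-CA, CA-C', C'=O), peptide bond
    C'(i)-N(i+1) within contiguous segments, 1-3 distances standing in for
    the backbone angles, SC-to-CA tethers (proline heavy-atom beads are
    chained CA->bead->bead), and every detected gap restraint at
    k = 100 kcal/(mol A^2).  The restraint energy of the input is zero except
    for gap restraints, which are also zero by construction.
    """
    k = dict(STIFFNESS)
    if stiffness:
        k.update(stiffness)
    lookup = _bead_lookup(complex)
    pairs: list[tuple[int, int, float]] = []  # (a, b, force constant)

    def add(a: int | None, b: int | None, kind: str) -> None:
        if a is not None and b is not None:
            pairs.append((a, b, k[kind]))

    def bead(res: int, role: int) -> int | None:
        return lookup.get((res, role))

    for start, stop in complex.segments:
        for r in range(start, stop):
            n, h = bead(r, ROLE_N), bead(r, ROLE_H)
            ca, c, o = bead(r, ROLE_CA), bead(r, ROLE_CPRIME), bead(r, ROLE_O)
            add(n, h, "bond")
            add(n, ca, "bond")
            add(ca, c, "bond")
            add(c, o, "bond")
            add(n, c, "angle")      # N-CA-C'
            add(ca, o, "angle")     # CA-C'=O
            add(h, ca, "angle")     # H-N-CA
            sc = bead(r, ROLE_SC)
            if sc is not None:
                add(sc, ca, "tether")
                add(sc, n, "tether")
            prev = None
            for b in range(complex.n_beads):
                if complex.bead_residue[b] == r and \
                        complex.bead_role[b] == ROLE_PRO_HEAVY:
                    add(ca if prev is None else prev, b, "tether")
                    prev = b
            if r + 1 < stop:
                n1, ca1 = bead(r + 1, ROLE_N), bead(r + 1, ROLE_CA)
                add(c, n1, "bond")      # peptide bond
                add(ca, n1, "angle")    # CA-C'-N
                add(c, ca1, "angle")    # C'-N-CA
                add(o, n1, "angle")     # O=C'...N
            if r + 2 < stop:
                # 1-4 CA-CA restraint standing in for backbone dihedrals,
                # which the harmonic scaffold otherwise leaves soft
                add(ca, bead(r + 2, ROLE_CA), "torsion")
    idx_a = np.array([p[0] for p in pairs], dtype=int)
    idx_b = np.array([p[1] for p in pairs], dtype=int)
    kk = np.array([p[2] for p in pairs], dtype=float)
    d0 = np.linalg.norm(complex.bead_pos[idx_a] - complex.bead_pos[idx_b], axis=1)
    for g in complex.gap_restraints:
        idx_a = np.append(idx_a, g.bead_a)
        idx_b = np.append(idx_b, g.bead_b)
        d0 = np.append(d0, g.equilibrium)
        kk = np.append(kk, g.force_constant)
    return RestraintSet(idx_a, idx_b, d0, kk)


# ---------------------------------------------------------------------------
# Nonbonded pair list and energy model
# ---------------------------------------------------------------------------

@dataclass
class _PairModel:
    """Precomputed nonbonded interaction list (static over one minimization)."""

    # harmonic restraints
    h_a: np.ndarray
    h_b: np.ndarray
    h_d0: np.ndarray
    h_k: np.ndarray
    # vdW 12-6 pairs
    v_a: np.ndarray
    v_b: np.ndarray
    v_radius: np.ndarray
    v_depth: np.ndarray
    # E_SS attractive pairs
    sa_a: np.ndarray
    sa_b: np.ndarray
    sa_eps: np.ndarray
    sa_sigma: np.ndarray
    sa_lambda: np.ndarray
    # E_SS repulsive pairs
    sr_a: np.ndarray
    sr_b: np.ndarray
    sr_eps: np.ndarray
    sr_sigma: np.ndarray
    # salt-bridge pairs, grouped by profile
    sb_groups: list  # (profile, idx_a, idx_b)

    def energy_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        pos = x.reshape(-1, 3)
        grad = np.zeros_like(pos)
        total = 0.0

        def accumulate(a, b, dEdr, r, dv):
            gvec = (dEdr / r)[:, None] * dv
            np.add.at(grad, a, gvec)
            np.add.at(grad, b, -gvec)

        if self.h_a.size:
            dv = pos[self.h_a] - pos[self.h_b]
            r = np.linalg.norm(dv, axis=1)
            diff = r - self.h_d0
            total += float(np.sum(self.h_k * diff ** 2))
            accumulate(self.h_a, self.h_b, 2.0 * self.h_k * diff, r, dv)
        if self.v_a.size:
            dv = pos[self.v_a] - pos[self.v_b]
            r = np.linalg.norm(dv, axis=1)
            x6 = (self.v_radius / r) ** 6
            total += float(np.sum(self.v_depth * (x6 * x6 - 2.0 * x6)))
            dEdr = -12.0 * self.v_depth / r * (x6 * x6 - x6)
            accumulate(self.v_a, self.v_b, dEdr, r, dv)
        if self.sa_a.size:
            dv = pos[self.sa_a] - pos[self.sa_b]
            r = np.linalg.norm(dv, axis=1)
            x6 = (self.sa_sigma / r) ** 6
            core = self.sa_eps * (x6 * x6 - 2.0 * x6)
            dcore = -12.0 * self.sa_eps / r * (x6 * x6 - x6)
            u = np.maximum(r - self.sa_sigma, 0.0) / self.sa_lambda
            s = 1.0 / (1.0 + u ** 6)
            ds = -6.0 * u ** 5 / self.sa_lambda * s * s
            total += float(np.sum(core * s))
            accumulate(self.sa_a, self.sa_b, dcore * s + core * ds, r, dv)
        if self.sr_a.size:
            dv = pos[self.sr_a] - pos[self.sr_b]
            r = np.linalg.norm(dv, axis=1)
            e = self.sr_eps * (self.sr_sigma / r) ** 6
            total += float(np.sum(e))
            accumulate(self.sr_a, self.sr_b, -6.0 * e / r, r, dv)
        for prof, a, b in self.sb_groups:
            dv = pos[a] - pos[b]
            r = np.linalg.norm(dv, axis=1)
            total += float(np.sum(prof(r)))
            accumulate(a, b, np.asarray(prof.derivative(r)), r, dv)
        if not np.isfinite(total) or not np.all(np.isfinite(grad)):
            bad = np.nonzero(~np.isfinite(grad).all(axis=1))[0]
            raise MinimizationError(
                f"non-finite energy/gradient (beads {bad[:5].tolist()}...)")
        return total, grad.ravel()


def _build_pair_model(complex: CGComplex, restraints: RestraintSet,
                      config: ForceFieldConfig, buffer: float = 2.0) -> _PairModel:
    pos = complex.bead_pos
    n = complex.n_beads
    role = complex.bead_role
    resid = complex.bead_residue
    rtype = complex.residue_type
    chain = complex.residue_chain
    center = complex.is_center()
    cutoff = config.cutoff

    ii, jj = np.triu_indices(n, k=1)
    # Exclude intra-residue pairs and pairs of adjacent residues in a chain
    # (their geometry is held by the scaffold).
    ri, rj = resid[ii], resid[jj]
    same_chain = chain[ri] == chain[rj]
    excl = (ri == rj) | (same_chain & (np.abs(ri - rj) <= 1))
    keep = ~excl
    if cutoff is not None:
        d = np.linalg.norm(pos[ii] - pos[jj], axis=1)
        keep &= d <= (cutoff + buffer)
    ii, jj = ii[keep], jj[keep]
    ri, rj = resid[ii], resid[jj]

    role_i, role_j = role[ii], role[jj]
    cc = center[ii] & center[jj]
    not_hb_dummy = (role_i != ROLE_H) & (role_j != ROLE_H) & \
                   (role_i != ROLE_PRO_HEAVY) & (role_j != ROLE_PRO_HEAVY)
    vdw_mask = ~cc & not_hb_dummy

    radius = np.zeros(vdw_mask.sum())
    depth = np.zeros(vdw_mask.sum())
    va, vb = ii[vdw_mask], jj[vdw_mask]
    for k, (a, b) in enumerate(zip(role[va], role[vb])):
        rada, da = config.vdw[int(a)]
        radb, db = config.vdw[int(b)]
        radius[k] = rada + radb
        depth[k] = np.sqrt(da * db)

    ti, tj = rtype[ri], rtype[rj]
    sbm = _SB_MASK[ti, tj] & cc
    table = config.pair_table
    att = cc & ~sbm & table.attractive[ti, tj]
    rep = cc & ~sbm & ~table.attractive[ti, tj]

    sb_groups = []
    for pid, prof in config.sb_profiles.items():
        from .residues import RESIDUE_TYPES
        na, nb = pid.split("-")
        a_t, b_t = RESIDUE_TYPES.index(na), RESIDUE_TYPES.index(nb)
        m = sbm & (((ti == a_t) & (tj == b_t)) | ((ti == b_t) & (tj == a_t)))
        if np.any(m):
            sb_groups.append((prof, ii[m], jj[m]))

    return _PairModel(
        h_a=restraints.idx_a, h_b=restraints.idx_b,
        h_d0=restraints.equilibrium, h_k=restraints.force_constant,
        v_a=va, v_b=vb, v_radius=radius, v_depth=depth,
        sa_a=ii[att], sa_b=jj[att],
        sa_eps=table.eps[ti[att], tj[att]],
        sa_sigma=table.sigma[ti[att], tj[att]],
        sa_lambda=damping_length(table.r0[ti[att], tj[att]]),
        sr_a=ii[rep], sr_b=jj[rep],
        sr_eps=table.eps[ti[rep], tj[rep]],
        sr_sigma=table.sigma[ti[rep], tj[rep]],
        sb_groups=sb_groups,
    )


def minimize_cartesian(complex: CGComplex, restraints: RestraintSet,
                       config: ForceFieldConfig,
                       n_steps: int = DEFAULT_STEPS) -> MinimizationResult:
    """Relax all beads with at most ``n_steps`` L-BFGS iterations.

    Deterministic given identical inputs; the energy trace (input energy
    plus one entry per accepted step) is non-increasing.  The interaction
    list is fixed from the input pose for the duration of the run.
    """
    model = _build_pair_model(complex, restraints, config)
    x0 = complex.bead_pos.ravel().copy()
    trace = [model.energy_grad(x0)[0]]

    def callback(xk):
        trace.append(model.energy_grad(xk)[0])

    res = scipy_minimize(model.energy_grad, x0, jac=True, method="L-BFGS-B",
                         callback=callback,
                         options={"maxiter": n_steps, "maxcor": 10,
                                  "ftol": 1e-12, "gtol": 1e-10})
    n_taken = int(res.nit)
    positions = res.x.reshape(-1, 3)
    return MinimizationResult(
        positions=positions,
        energy_trace=np.asarray(trace[:n_taken + 1]),
        n_steps_taken=n_taken,
        converged=bool(res.success) or n_taken < n_steps,
    )
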