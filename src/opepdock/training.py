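"""Iterative contact-potential training of the 8-6 rescoring function.

Decoys of a target are classified by crossing hit status (IRMSD < 4 A) with
ranking status (rank <= 20): TP, FN, FP, TN.  Per complex class, residue-type
contact-frequency maps are averaged over the kept decoys of all targets; a
type pair whose contacts are more frequent among TP and FN decoys than among
FP and TN decoys is strengthened, the reverse is weakened, by shifting the
pair's well depth:

    E_new(i,j) = E_old(i,j) - k ln(FN_ij / FP_ij)

applied to the E_SS86 well depth, or to the salt-bridge profile depth for
the four salt-bridge type pairs.  Only well depths move; sigma' and the
functional forms are untouched.  Decoy geometries stay fixed between
iterations (re-scoring and re-ranking only, no re-minimization).  The number
of FN and FP decoys kept per target is capped at 20 - N (N = number of TPs);
targets with >= 20 hits contribute no FNs or FPs.  Training stops after a
fixed number of iterations, chosen by cross-validated log-rank quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cgmodel import CGComplex
from .evaluation import DecoySet, rank_and_best_hit
from .exceptions import OpepdockError
from .forcefield import ForceFieldConfig
from .residues import N_TYPES, RESIDUE_TYPES
from .softscore import SoftPairTable, score_e86, score_ss_sb_by_type

CONTACT_CUTOFF = 8.0   # Angstrom, strict: a contact needs distance < 8
RANK_CUTOFF = 20       # "top 20" threshold of the TP/FN/FP/TN grid
DEFAULT_K = 0.2
DEFAULT_ITERATIONS = 30

LABELS = ("TP", "FN", "FP", "TN")


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

def contact_map(complex: CGComplex) -> np.ndarray:
    """20x20 inter-partner residue-type contact counts for one decoy.

    Two residues (one per partner) are in contact iff any pair of their
    beads is closer than 8 A (strict).  Each contact increments the
    symmetric (type_i, type_j) cell.
    """
    rec = complex.partner_bead_indices(0)
    lig = complex.partner_bead_indices(1)
    return _contact_map_from_arrays(
        complex.bead_pos[rec], complex.bead_residue[rec],
        complex.bead_pos[lig], complex.bead_residue[lig],
        complex.residue_type)


def _contact_map_from_arrays(rec_pos, rec_resid, lig_pos, lig_resid,
                             residue_type) -> np.ndarray:
    tree = cKDTree(rec_pos)
    neighbours = tree.query_ball_point(lig_pos, CONTACT_CUTOFF)
    pairs = set()
    for lk, rec_list in enumerate(neighbours):
        if not rec_list:
            continue
        lr = int(lig_resid[lk])
        # strict inequality: discard pairs at exactly the cutoff
        for rk in rec_list:
            d = np.linalg.norm(lig_pos[lk] - rec_pos[rk])
            if d < CONTACT_CUTOFF:
                pairs.add((int(rec_resid[rk]), lr))
    out = np.zeros((N_TYPES, N_TYPES), dtype=np.int32)
    for rr, lr in pairs:
        a, b = int(residue_type[rr]), int(residue_type[lr])
        out[a, b] += 1
        if a != b:
            out[b, a] += 1
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_predictions(ranking: pd.DataFrame) -> pd.DataFrame:
    """Label each ranked decoy TP/FN/FP/TN and apply the 20-N keep caps.

    Returns the ranking table with ``label`` and ``kept`` columns.  All TPs
    (there are at most 20) are kept; the best-ranked 20-N FNs and FPs are
    kept; all TNs are kept.  Targets with >= 20 hits in total keep no FNs or
    FPs at all.
    """
    df = ranking.copy()
    top = df["rank"] <= RANK_CUTOFF
    df["label"] = np.where(df["hit"] & top, "TP",
                   np.where(df["hit"] & ~top, "FN",
                    np.where(~df["hit"] & top, "FP", "TN")))
    n_tp = int((df["label"] == "TP").sum())
    total_hits = int(df["hit"].sum())
    budget = 0 if total_hits >= RANK_CUTOFF else RANK_CUTOFF - n_tp
    df["kept"] = df["label"].isin(("TP", "TN"))
    for lab in ("FN", "FP"):
        idx = df.index[df["label"] == lab]  # already rank-sorted
        df.loc[idx[:budget], "kept"] = True
    return df


@dataclass
class ContactFrequencyMaps:
    """Class-averaged per-decoy-mean contact maps for the four labels."""

    maps: dict[str, np.ndarray]
    counts: dict[str, int]

    def empty(self, label: str) -> bool:
        return self.counts[label] == 0

    @property
    def total_kept(self) -> int:
        return sum(self.counts.values())


def accumulate_frequency_maps(classified: list[pd.DataFrame],
                              maps_per_target: list[np.ndarray]
                              ) -> ContactFrequencyMaps:
    """Average contact maps per label over kept decoys of all targets.

    ``maps_per_target[t]`` holds the (n_decoys, 20, 20) contact maps of
    target ``t`` indexed by decoy position in the *unranked* decoy order;
    the classified tables carry that order in their ``decoy_index`` column.
    """
    sums = {lab: np.zeros((N_TYPES, N_TYPES)) for lab in LABELS}
    counts = {lab: 0 for lab in LABELS}
    for df, maps in zip(classified, maps_per_target):
        kept = df[df["kept"]]
        for lab in LABELS:
            rows = kept[kept["label"] == lab]
            if len(rows):
                sums[lab] += maps[rows["decoy_index"].to_numpy()].sum(axis=0)
                counts[lab] += len(rows)
    mean_maps = {
        lab: (sums[lab] / counts[lab]) if counts[lab] else sums[lab]
        for lab in LABELS
    }
    return ContactFrequencyMaps(maps=mean_maps, counts=counts)


# ---------------------------------------------------------------------------
# Potential state and the update rule
# ---------------------------------------------------------------------------

def initial_well_depths(soft: SoftPairTable,
                        config: ForceFieldConfig) -> np.ndarray:
    """20x20 matrix of minimum energies addressed by the training update.

    Attractive E_SS86 entries: -eps (the common minimum of E_SS and
    E_SS86); repulsive-only entries: the value at sigma (+eps); the four
    salt-bridge type pairs: the minimum of their tabulated profile.
    """
    table = soft.base_table
    w = np.where(table.attractive, -table.eps, table.eps).astype(float)
    for pid, prof in config.sb_profiles.items():
        na, nb = pid.split("-")
        a, b = RESIDUE_TYPES.index(na), RESIDUE_TYPES.index(nb)
        w[a, b] = w[b, a] = prof.minimum_energy()
    return w


@dataclass
class TrainedPotential:
    """Iteratively updated well-depth matrix E_X(i, j) per complex class."""

    well_depths: np.ndarray         # current W
    initial_depths: np.ndarray      # W at iteration 0
    k: float = DEFAULT_K
    iterations: int = 0
    complex_class: str = "other"
    snapshots: list[np.ndarray] = field(default_factory=list)

    @classmethod
    def fresh(cls, soft: SoftPairTable, config: ForceFieldConfig,
              complex_class: str = "other", k: float = DEFAULT_K
              ) -> "TrainedPotential":
        w0 = initial_well_depths(soft, config)
        return cls(well_depths=w0.copy(), initial_depths=w0, k=k,
                   complex_class=complex_class)

    def scale_matrix(self) -> np.ndarray:
        """Per-type-pair energy scale W/W0 (functional forms unchanged)."""
        return self.well_depths / self.initial_depths

    def apply(self, soft: SoftPairTable, config: ForceFieldConfig
              ) -> tuple[SoftPairTable, ForceFieldConfig]:
        """Materialize the trained potential as scaled parameter tables."""
        import copy as _copy

        scale = self.scale_matrix()
        table = soft.base_table.copy()
        table.eps = np.abs(table.eps * scale)
        new_soft = SoftPairTable(
            sigma_prime=soft.sigma_prime.copy(),
            eps_prime=soft.eps_prime * np.abs(scale),
            attractive=soft.attractive.copy(),
            base_table=table, vdw_soft=dict(soft.vdw_soft))
        new_config = _copy.copy(config)
        new_config.sb_profiles = {}
        for pid, prof in config.sb_profiles.items():
            na, nb = pid.split("-")
            a, b = RESIDUE_TYPES.index(na), RESIDUE_TYPES.index(nb)
            new_config.sb_profiles[pid] = prof.scaled(float(scale[a, b]))
        return new_soft, new_config


def select_and_update(maps: ContactFrequencyMaps, potential: TrainedPotential,
                      k: float | None = None) -> TrainedPotential:
    """One iteration of the frequency-ratio update (applied symmetrically).

    A pair is selected for strengthening iff its frequency is strictly
    higher in both the TP and FN maps than in both the FP and TN maps, and
    for weakening iff all four inequalities are strictly reversed; ties
    deselect.  Selected entries move by -k ln(FN/FP) with an additive
    pseudocount of 1/(total kept decoys) guarding zero frequencies.
    """
    k = potential.k if k is None else k
    if maps.empty("FN") or maps.empty("FP"):
        # The FN/FP ratio is undefined when either class kept no decoys
        # (e.g. every hit already ranks in the top 20, so no FNs are kept);
        # the iteration applies no update.
        potential.iterations += 1
        potential.snapshots.append(potential.well_depths.copy())
        return potential
    tp, fn = maps.maps["TP"], maps.maps["FN"]
    fp, tn = maps.maps["FP"], maps.maps["TN"]
    # Classes with zero kept decoys contribute no inequality: their maps
    # carry no frequency information, only the populated classes vote.
    true_m = np.ones_like(fn, dtype=bool)
    tp_gt_fp = (tp > fp) if not maps.empty("TP") else true_m
    tp_gt_tn = (tp > tn) if not (maps.empty("TP") or maps.empty("TN")) else true_m
    fn_gt_tn = (fn > tn) if not maps.empty("TN") else true_m
    tp_lt_fp = (tp < fp) if not maps.empty("TP") else true_m
    tp_lt_tn = (tp < tn) if not (maps.empty("TP") or maps.empty("TN")) else true_m
    fn_lt_tn = (fn < tn) if not maps.empty("TN") else true_m
    strengthen = tp_gt_fp & tp_gt_tn & (fn > fp) & fn_gt_tn
    weaken = tp_lt_fp & tp_lt_tn & (fn < fp) & fn_lt_tn
    selected = strengthen | weaken
    eps_f = 1.0 / maps.total_kept if maps.total_kept else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = k * np.log((fn + eps_f) / (fp + eps_f))
    w = potential.well_depths.copy()
    w[selected] -= shift[selected]
    potential.well_depths = w
    potential.iterations += 1
    potential.snapshots.append(w.copy())
    return potential


# ---------------------------------------------------------------------------
# Target caches and the training loop
# ---------------------------------------------------------------------------

@dataclass
class TargetCache:
    """Per-target precomputation enabling cheap re-scoring.

    The SS86/SB part of E_86 is linear in the per-type-pair well depths, so
    each decoy's score under a trained potential is
    ``fixed + sum_(a<=b) scale[a,b] * features[a,b]`` where ``features``
    accumulates the decoy's unscaled per-type-pair SS86/SB energy.
    """

    target_id: str
    decoy_ids: list[str]
    irmsd: np.ndarray
    fixed: np.ndarray           # (n_decoys,) e_vdw86 + e_hb
    features: np.ndarray        # (n_decoys, 20, 20), upper triangle (a <= b)
    contact_maps: np.ndarray    # (n_decoys, 20, 20) int

    def scores(self, scale: np.ndarray) -> np.ndarray:
        iu = np.triu_indices(N_TYPES)
        return self.fixed + self.features[:, iu[0], iu[1]] @ scale[iu]


def build_target_cache(decoys: DecoySet, soft: SoftPairTable,
                       config: ForceFieldConfig) -> TargetCache:
    """Precompute per-decoy features, fixed energies and contact maps."""
    ref = decoys.reference
    rec = ref.partner_bead_indices(0)
    lig_beads = decoys.ligand_bead_indices()
    center = ref.is_center()
    rec_centers = rec[center[rec]]
    lig_center_local = np.nonzero(center[lig_beads])[0]
    rt = ref.residue_type
    rec_c_types = rt[ref.bead_residue[rec_centers]]
    lig_c_types = rt[ref.bead_residue[lig_beads[lig_center_local]]]
    rec_c_pos = ref.bead_pos[rec_centers]

    rec_resid = ref.bead_residue[rec]
    rec_pos = ref.bead_pos[rec]
    lig_resid = ref.bead_residue[lig_beads]

    if decoys.irmsd is None:
        raise OpepdockError("decoy set lacks stored IRMSDs")

    n = decoys.n_decoys
    fixed = np.zeros(n)
    features = np.zeros((n, N_TYPES, N_TYPES))
    cmaps = np.zeros((n, N_TYPES, N_TYPES), dtype=np.int32)
    for i in range(n):
        dc = decoys.decoy_complex(i)
        bd = score_e86(dc, soft, config)
        fixed[i] = bd.e_vdw86 + bd.e_hb
        lig_pos = decoys.ligand_positions[i]
        # per-type-pair SS86/SB features over center pairs
        lc = lig_pos[lig_center_local]
        diff = rec_c_pos[:, None, :] - lc[None, :, :]
        d = np.linalg.norm(diff, axis=2).ravel()
        ti = np.repeat(rec_c_types, len(lig_center_local))
        tj = np.tile(lig_c_types, len(rec_c_types))
        if config.cutoff is not None:
            keep = d <= config.cutoff
            d, ti, tj = d[keep], ti[keep], tj[keep]
        per = score_ss_sb_by_type(d, ti, tj, soft, config)
        e_pair = per["ss86"] + per["sb"]
        a = np.minimum(ti, tj)
        b = np.maximum(ti, tj)
        np.add.at(features[i], (a, b), e_pair)
        cmaps[i] = _contact_map_from_arrays(rec_pos, rec_resid, lig_pos,
                                            lig_resid, rt)
    return TargetCache(target_id=decoys.target_id,
                       decoy_ids=list(decoys.decoy_ids),
                       irmsd=np.asarray(decoys.irmsd, dtype=float),
                       fixed=fixed, features=features, contact_maps=cmaps)


def _rank_target(cache: TargetCache, scale: np.ndarray
                 ) -> tuple[pd.DataFrame, int | None]:
    scores = cache.scores(scale)
    df, best = rank_and_best_hit(cache.decoy_ids, scores, cache.irmsd)
    order = {d: i for i, d in enumerate(cache.decoy_ids)}
    df["decoy_index"] = df["decoy_id"].map(order)
    return df, best


def train(targets: list[TargetCache], soft: SoftPairTable,
          config: ForceFieldConfig, complex_class: str = "other",
          iterations: int = DEFAULT_ITERATIONS, k: float = DEFAULT_K
          ) -> TrainedPotential:
    """Run the iterative update on one complex class.

    Each iteration re-ranks every target with the current well depths,
    classifies, accumulates the class-averaged frequency maps and applies
    the selection/update rule.  Deterministic given inputs.
    """
    if not targets:
        raise OpepdockError(f"no targets for class {complex_class!r}")
    potential = TrainedPotential.fresh(soft, config, complex_class, k)
    for _ in range(iterations):
        scale = potential.scale_matrix()
        classified = []
        maps = []
        for cache in targets:
            df, _ = _rank_target(cache, scale)
            classified.append(classify_predictions(df))
            maps.append(cache.contact_maps)
        freq = accumulate_frequency_maps(classified, maps)
        potential = select_and_update(freq, potential, k)
    return potential


def mean_best_hit_rank(targets: list[TargetCache], scale: np.ndarray,
                       policy: str = "substitute_2000") -> float:
    from .evaluation import summarize_mean_rank

    ranks = [_rank_target(c, scale)[1] for c in targets]
    return summarize_mean_rank(ranks, policy)


def validation_quality(targets: list[TargetCache], scale: np.ndarray) -> float:
    """Sum of ln(best-hit rank) over targets (hits assumed to exist)."""
    total = 0.0
    for cache in targets:
        _, best = _rank_target(cache, scale)
        if best is None:
            best = 2000  # no hit: contribute the cap's log
        total += float(np.log(best))
    return total


@dataclass
class CVReport:
    fold_assignments: list[np.ndarray]
    quality_per_iteration: np.ndarray  # (folds, iterations + 1)
    chosen_iteration: int
    overfitting: bool


def cross_validate(targets: list[TargetCache], soft: SoftPairTable,
                   config: ForceFieldConfig, folds: int = 4,
                   iterations_max: int = DEFAULT_ITERATIONS,
                   k: float = DEFAULT_K, seed: int = 0) -> CVReport:
    """Seeded k-fold cross-validation of the training iteration count.

    Per fold: train on the complement, evaluate the log-rank quality on the
    held-out targets after every iteration; the chosen iteration minimizes
    the mean validation quality (iteration 0 = untrained).  A final quality
    above its running minimum flags overfitting.
    """
    n = len(targets)
    if n < folds:
        raise OpepdockError(f"need >= {folds} targets for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = [np.sort(perm[f::folds]) for f in range(folds)]
    quality = np.zeros((folds, iterations_max + 1))
    for f, val_idx in enumerate(assignments):
        val = [targets[i] for i in val_idx]
        tr = [targets[i] for i in range(n) if i not in set(val_idx.tolist())]
        potential = TrainedPotential.fresh(soft, config, k=k)
        quality[f, 0] = validation_quality(val, potential.scale_matrix())
        for it in range(1, iterations_max + 1):
            scale = potential.scale_matrix()
            classified, maps = [], []
            for cache in tr:
                df, _ = _rank_target(cache, scale)
                classified.append(classify_predictions(df))
                maps.append(cache.contact_maps)
            freq = accumulate_frequency_maps(classified, maps)
            potential = select_and_update(freq, potential, k)
            quality[f, it] = validation_quality(val, potential.scale_matrix())
    mean_quality = quality.mean(axis=0)
    chosen = int(np.argmin(mean_quality))
    overfitting = bool(mean_quality[-1] > mean_quality.min() + 1e-12)
    return CVReport(fold_assignments=assignments,
                    quality_per_iteration=quality,
                    chosen_iteration=chosen,
                    overfitting=overfitting)


def delta_matrix(trained: TrainedPotential) -> np.ndarray:
    """20x20 change in minimum energy produced by training.

    Sign convention: trained minus initial, so negative entries mean the
    interaction became *more attractive* (deeper well); the published
    difference maps use the same colour reading.  Output headers record the
    convention.
    """
    return trained.well_depths - trained.initial_depths


def delta_matrix_frame(trained: TrainedPotential) -> pd.DataFrame:
    from .residues import ONE_LETTER

    letters = [ONE_LETTER[r] for r in RESIDUE_TYPES]
    return pd.DataFrame(delta_matrix(trained), index=letters, columns=letters)
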