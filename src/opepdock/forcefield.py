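"""OPEP-style nonbonded functional forms and their parameter tables.

Four inter-partner terms are modelled: a 12-6 van der Waals potential for
pairs involving backbone beads (E_VDW), hydrophobic/hydrophilic side chain -
side chain interactions (E_SS) evaluated between interaction centers,
backbone N-H...O=C' hydrogen bonds (E_HB), and tabulated free-energy
profiles for the four salt-bridge pairs (E_SB).

E_SS is branch-split by an attractive/repulsive flag stored alongside the
positive interaction magnitude eps_ij (avoiding any ambiguity about how the
repulsive branch encodes its sign).  The attractive branch is a 12-6 well
with minimum exactly -eps_ij at sigma_ij, multiplied beyond sigma_ij by a
smooth long-range damper whose length scale is set by the sixth root of the
damping function G(r0); the repulsive branch is a bare (sigma/r)^6 decay.
sigma_ij derives from the tabulated optimal distance r0_ij through the
linear map sigma = 1.0729 r0 - 0.3992.

All numeric parameters live in an editable text file (see
:func:`save_forcefield` for the schema); the shipped default table is a
documented stand-in built from residue size/stickiness scales, not the
original OPEPv5 values, and can be substituted wholesale by the user.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.interpolate import PchipInterpolator

from .cgmodel import ROLE_CA, ROLE_CPRIME, ROLE_N, ROLE_O, ROLE_SC
from .exceptions import GeometryError, ParameterError
from .residues import (
    N_TYPES,
    NEGATIVE,
    POSITIVE,
    RESIDUE_TYPES,
    SALT_BRIDGE_PAIRS,
    SIDECHAIN_RADIUS,
    STICKINESS,
    TYPE_INDEX,
    is_salt_bridge_pair,
)

SIGMA_SLOPE = 1.0729
SIGMA_INTERCEPT = 0.3992


def sigma_from_r0(r0):
    """Equilibrium distance sigma from the tabulated optimum r0 (Angstrom).

    sigma = 1.0729 r0 - 0.3992; raises for non-positive input or output.
    """
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 <= 0):
        raise ParameterError("r0 must be positive")
    sigma = SIGMA_SLOPE * r0 - SIGMA_INTERCEPT
    if np.any(sigma <= 0):
        raise ParameterError("sigma = 1.0729 r0 - 0.3992 must be positive")
    return float(sigma) if sigma.ndim == 0 else sigma


def long_range_damping(r0):
    """G(r0) = [-0.7 e^(2 (r0-0.5)/5.0) (r0-0.5)]^6 (dimensionless, >= 0)."""
    r0 = np.asarray(r0, dtype=float)
    base = -0.7 * np.exp(2.0 * (r0 - 0.5) / 5.0) * (r0 - 0.5)
    g = base ** 6
    return float(g) if g.ndim == 0 else g


def damping_length(r0):
    """Length scale lambda = G(r0)^(1/6) of the long-range damper (Angstrom)."""
    r0 = np.asarray(r0, dtype=float)
    lam = np.abs(0.7 * np.exp(2.0 * (r0 - 0.5) / 5.0) * (r0 - 0.5))
    return float(lam) if lam.ndim == 0 else lam


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class PairParameterTable:
    """20x20 symmetric side chain - side chain interaction parameters.

    ``eps`` holds positive magnitudes (kcal/mol); ``attractive`` flags select
    the E_SS branch.  ``sigma`` is derived from ``r0`` entrywise.
    """

    eps: np.ndarray          # (20, 20) >= 0, kcal/mol
    attractive: np.ndarray   # (20, 20) bool
    r0: np.ndarray           # (20, 20) Angstrom
    provenance: str = ""

    def __post_init__(self) -> None:
        for name in ("eps", "attractive", "r0"):
            m = getattr(self, name)
            if m.shape != (N_TYPES, N_TYPES):
                raise ParameterError(f"{name} must be {N_TYPES}x{N_TYPES}")
            if not np.array_equal(m, m.T):
                raise ParameterError(f"{name} must be symmetric")
        if np.any(self.eps < 0):
            raise ParameterError("eps stores magnitudes and must be >= 0")
        if np.any(self.r0 <= 0):
            raise ParameterError("r0 must be positive")
        self.sigma = sigma_from_r0(self.r0)

    def copy(self) -> "PairParameterTable":
        return PairParameterTable(self.eps.copy(), self.attractive.copy(),
                                  self.r0.copy(), self.provenance)


@dataclass
class SaltBridgeProfile:
    """Tabulated salt-bridge free-energy profile (kcal/mol vs Angstrom).

    Arg pairs have one interior minimum, Lys pairs two (contact and
    solvent-separated wells).  The profile is interpolated with a monotone
    cubic (PCHIP); the energy is zero beyond the last grid point and clamped
    to the first tabulated value below the grid (repulsive wall).
    """

    pair: str                 # e.g. "ARG-ASP"
    distance_grid: np.ndarray
    energy: np.ndarray
    n_minima: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.distance_grid) <= 0):
            raise ParameterError("salt-bridge grid must be strictly increasing")
        if self.n_minima not in (1, 2):
            raise ParameterError("n_minima must be 1 or 2")
        self._spline = PchipInterpolator(self.distance_grid, self.energy,
                                         extrapolate=False)
        self._dspline = self._spline.derivative()

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        out = np.where(r < self.distance_grid[0], self.energy[0],
                       np.where(r > self.distance_grid[-1], 0.0,
                                np.nan_to_num(self._spline(
                                    np.clip(r, self.distance_grid[0],
                                            self.distance_grid[-1])))))
        return float(out) if out.ndim == 0 else out

    def derivative(self, r):
        r = np.asarray(r, dtype=float)
        inside = (r >= self.distance_grid[0]) & (r <= self.distance_grid[-1])
        d = np.nan_to_num(self._dspline(np.clip(r, self.distance_grid[0],
                                                self.distance_grid[-1])))
        out = np.where(inside, d, 0.0)
        return float(out) if out.ndim == 0 else out

    def minimum_energy(self) -> float:
        grid = np.linspace(self.distance_grid[0], self.distance_grid[-1], 2001)
        return float(np.min(self._spline(grid)))

    def interior_minima(self) -> int:
        """Count interior minima via sign changes of the numerical derivative."""
        grid = np.linspace(self.distance_grid[0], self.distance_grid[-1], 4001)
        d = self._dspline(grid)
        sign = np.sign(d)
        nz = sign != 0
        changes = np.diff(sign[nz])
        return int(np.sum(changes > 0))

    def scaled(self, factor: float) -> "SaltBridgeProfile":
        return SaltBridgeProfile(self.pair, self.distance_grid.copy(),
                                 self.energy * factor, self.n_minima)


@dataclass(frozen=True)
class HBondParams:
    """Backbone H-bond parameters (N-H donor, C'=O acceptor)."""

    well_depth: float = -1.5          # kcal/mol, < 0
    equilibrium_short: float = 1.8    # Angstrom, sequence separation < 5
    equilibrium_long: float = 2.0     # Angstrom, separation > 4 / inter-partner
    angular_exponent: float = 2.0
    cutoff: float = 8.0               # Angstrom (H...O distance)

    def __post_init__(self) -> None:
        if self.well_depth >= 0:
            raise ParameterError("H-bond well depth must be negative")
        if self.equilibrium_short <= 0 or self.equilibrium_long <= 0:
            raise ParameterError("H-bond equilibrium distances must be positive")


#: Per-role van der Waals radius (Angstrom) and depth (kcal/mol).  H beads
#: participate only in E_HB; proline heavy-atom beads are geometry-only.
DEFAULT_VDW: dict[int, tuple[float, float]] = {
    ROLE_N: (1.6, 0.12),
    ROLE_CA: (2.0, 0.10),
    ROLE_CPRIME: (1.7, 0.12),
    ROLE_O: (1.5, 0.15),
    ROLE_SC: (2.2, 0.08),
}


@dataclass
class ForceFieldConfig:
    """Validated bundle of every parameter of the scoring function."""

    pair_table: PairParameterTable
    sb_profiles: dict[str, SaltBridgeProfile]
    hb: HBondParams = field(default_factory=HBondParams)
    vdw: dict[int, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_VDW))
    cutoff: float | None = 16.0  # global nonbonded cutoff, shifted to zero

    def __post_init__(self) -> None:
        expected = {f"{a}-{b}" for a, b in SALT_BRIDGE_PAIRS}
        if set(self.sb_profiles) != expected:
            raise ParameterError(f"salt-bridge profiles must cover {sorted(expected)}")

    def checksum(self) -> str:
        """Stable digest of all parameters, recorded in outputs."""
        h = hashlib.sha256()
        t = self.pair_table
        for arr in (t.eps, t.attractive.astype(np.int8), t.r0):
            h.update(np.ascontiguousarray(arr).tobytes())
        for key in sorted(self.sb_profiles):
            p = self.sb_profiles[key]
            h.update(key.encode())
            h.update(p.distance_grid.tobytes())
            h.update(p.energy.tobytes())
        h.update(repr((self.hb, sorted(self.vdw.items()), self.cutoff)).encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pair energies
# ---------------------------------------------------------------------------

def ess_pair(r, i: int, j: int, table: PairParameterTable):
    """Side chain - side chain energy E_SS(r) for residue types (i, j).

    Attractive branch: eps * [(sigma/r)^12 - 2 (sigma/r)^6], damped beyond
    sigma by S(r) = 1 / (1 + ((r - sigma)/lambda)^6) with lambda = G(r0)^(1/6);
    the damper leaves both the minimum location (sigma) and depth (-eps)
    exact while limiting the attraction at longer distances.
    Repulsive branch: eps * (sigma/r)^6, non-negative and monotone to zero.
    Salt-bridge type pairs are not handled here (they route to esb_pair).
    """
    if is_salt_bridge_pair(i, j):
        raise ParameterError(
            f"{RESIDUE_TYPES[i]}/{RESIDUE_TYPES[j]} is a salt-bridge pair; "
            "use esb_pair")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ParameterError("r must be positive")
    eps = table.eps[i, j]
    sigma = table.sigma[i, j]
    if table.attractive[i, j]:
        x6 = (sigma / r) ** 6
        core = eps * (x6 * x6 - 2.0 * x6)
        lam = damping_length(table.r0[i, j])
        u = np.maximum(r - sigma, 0.0) / lam
        out = core / (1.0 + u ** 6)
    else:
        out = eps * (sigma / r) ** 6
    return float(out) if out.ndim == 0 else out


def ess_pair_derivative(r, i: int, j: int, table: PairParameterTable):
    """dE_SS/dr for the minimizer's analytic gradient."""
    r = np.asarray(r, dtype=float)
    eps = table.eps[i, j]
    sigma = table.sigma[i, j]
    if table.attractive[i, j]:
        x6 = (sigma / r) ** 6
        core = eps * (x6 * x6 - 2.0 * x6)
        dcore = -12.0 * eps / r * (x6 * x6 - x6)
        lam = damping_length(table.r0[i, j])
        u = np.maximum(r - sigma, 0.0) / lam
        s = 1.0 / (1.0 + u ** 6)
        ds = -6.0 * u ** 5 / lam * s * s
        out = dcore * s + core * ds
    else:
        out = -6.0 * eps * sigma ** 6 / r ** 7
    return float(out) if out.ndim == 0 else out


def combine_vdw(role_a: int, role_b: int,
                vdw: dict[int, tuple[float, float]]) -> tuple[float, float]:
    """Combined 12-6 parameters: radius sum, geometric-mean depth."""
    ra, da = vdw[role_a]
    rb, db = vdw[role_b]
    return ra + rb, float(np.sqrt(da * db))


def evdw_pair(r, role_a: int, role_b: int, config: ForceFieldConfig):
    """Backbone-involving 12-6 van der Waals energy."""
    radius, depth = combine_vdw(role_a, role_b, config.vdw)
    r = np.asarray(r, dtype=float)
    x6 = (radius / r) ** 6
    out = depth * (x6 * x6 - 2.0 * x6)
    return float(out) if out.ndim == 0 else out


def ehb_pair(n_pos, h_pos, c_pos, o_pos, sequence_separation: int | None,
             params: HBondParams):
    """Backbone H-bond energy between an N-H donor and a C'=O acceptor.

    The energy is well_depth * radial * alignment, with the radial well equal
    to 1 exactly at the applicable equilibrium H...O distance (clamped at
    short range so the term is never positive) and an alignment factor
    cos(theta)^p that is 1 for colinear N-H...O and 0 at or beyond 90 deg.
    Inter-partner pairs have no defined sequence separation and use the
    "long" equilibrium distance.
    """
    n_pos = np.asarray(n_pos, float)
    h_pos = np.asarray(h_pos, float)
    o_pos = np.asarray(o_pos, float)
    hv = h_pos - n_pos
    hn = np.linalg.norm(hv)
    if hn < 1e-10:
        raise GeometryError("zero-length N-H vector")
    ho = o_pos - h_pos
    r = np.linalg.norm(ho)
    if r < 1e-10:
        raise GeometryError("zero-length H...O vector")
    if r > params.cutoff:
        return 0.0
    if sequence_separation is not None and 0 < abs(sequence_separation) < 5:
        r0 = params.equilibrium_short
    else:
        r0 = params.equilibrium_long
    x6 = (r0 / r) ** 6
    radial = max(2.0 * x6 - x6 * x6, 0.0)
    cos_t = float(np.dot(hv, ho) / (hn * r))
    align = max(cos_t, 0.0) ** params.angular_exponent
    return params.well_depth * radial * align


def esb_pair(r, pair_id: str, profiles: dict[str, SaltBridgeProfile]):
    """Salt-bridge energy from the tabulated profile (interaction centers)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ParameterError("r must be positive")
    out = profiles[pair_id](r)
    return out


# ---------------------------------------------------------------------------
# Default parameter construction
# ---------------------------------------------------------------------------

def _gaussian(r, center, depth, width):
    return -depth * np.exp(-((r - center) ** 2) / (2.0 * width ** 2))


def default_salt_bridge_profiles() -> dict[str, SaltBridgeProfile]:
    """Smooth Gaussian-well default profiles (documented stand-ins).

    One well for Arg/Asp and Arg/Glu, two wells (contact and
    solvent-separated) for Lys/Asp and Lys/Glu, plus a short-range
    exponential wall; sampled on a 2.5-10 A grid.
    """
    grid = np.round(np.arange(2.5, 10.0 + 1e-9, 0.25), 4)
    wall = 8.0 * np.exp(-(grid - 2.5) / 0.25)
    spec = {
        "ARG-ASP": [(4.0, 3.0, 0.6)],
        "ARG-GLU": [(4.2, 2.8, 0.6)],
        "LYS-ASP": [(3.5, 2.5, 0.45), (5.5, 1.2, 0.6)],
        "LYS-GLU": [(3.7, 2.3, 0.45), (5.7, 1.1, 0.6)],
    }
    profiles = {}
    for pair, wells in spec.items():
        energy = wall.copy()
        for center, depth, width in wells:
            energy = energy + _gaussian(grid, center, depth, width)
        profiles[pair] = SaltBridgeProfile(pair, grid, np.round(energy, 6),
                                           n_minima=len(wells))
    return profiles


def default_pair_table() -> PairParameterTable:
    """Construct the default 20x20 table from size/stickiness scales.

    Attraction magnitudes grow with the product of the two residues'
    stickiness; like-charged pairs are repulsive; weakly interacting pairs
    are mildly repulsive.  These are documented stand-in values in the style
    of the coarse-grained OPEP tables, not the original parameter set.
    """
    eps = np.zeros((N_TYPES, N_TYPES))
    attractive = np.zeros((N_TYPES, N_TYPES), dtype=bool)
    r0 = np.zeros((N_TYPES, N_TYPES))
    for a, ra in enumerate(RESIDUE_TYPES):
        for b, rb in enumerate(RESIDUE_TYPES):
            r0[a, b] = SIDECHAIN_RADIUS[ra] + SIDECHAIN_RADIUS[rb]
            like_charge = (ra in POSITIVE and rb in POSITIVE) or \
                          (ra in NEGATIVE and rb in NEGATIVE)
            magnitude = 0.8 * STICKINESS[ra] * STICKINESS[rb] + 0.05
            if like_charge:
                eps[a, b] = 0.25
                attractive[a, b] = False
            elif magnitude >= 0.12:
                eps[a, b] = magnitude
                attractive[a, b] = True
            else:
                eps[a, b] = 0.10
                attractive[a, b] = False
    eps = np.round(eps, 6)
    return PairParameterTable(
        eps=eps, attractive=attractive, r0=r0,
        provenance=("synthetic stand-in pair table v1: stickiness/size model; "
                    "not the published OPEPv5 values"))


def default_config(cutoff: float | None = 16.0) -> ForceFieldConfig:
    return ForceFieldConfig(
        pair_table=default_pair_table(),
        sb_profiles=default_salt_bridge_profiles(),
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# Parameter file I/O
# ---------------------------------------------------------------------------

_ROLE_BY_NAME = {"N": ROLE_N, "CA": ROLE_CA, "C": ROLE_CPRIME, "O": ROLE_O,
                 "SC": ROLE_SC}
_NAME_BY_ROLE = {v: k for k, v in _ROLE_BY_NAME.items()}


def save_forcefield(config: ForceFieldConfig, path) -> None:
    """Write the parameter file (sections [meta], [pairs], [saltbridge:*],
    [hbond], [vdw]; '#' comments; fixed six-decimal reals)."""
    t = config.pair_table
    lines = [
        "# opepdock force-field parameter file v1",
        "# harmonic restraint convention: E = k (d - d0)^2 (no 1/2)",
        f"# provenance: {t.provenance}",
        "[meta]",
        f"cutoff {config.cutoff if config.cutoff is not None else 'none'}",
        "[pairs]",
        "# resA resB eps(kcal/mol) branch r0(A)",
    ]
    for a in range(N_TYPES):
        for b in range(a, N_TYPES):
            branch = "attractive" if t.attractive[a, b] else "repulsive"
            lines.append(f"{RESIDUE_TYPES[a]} {RESIDUE_TYPES[b]} "
                         f"{t.eps[a, b]:.6f} {branch} {t.r0[a, b]:.6f}")
    for key in sorted(config.sb_profiles):
        p = config.sb_profiles[key]
        lines.append(f"[saltbridge:{key}]")
        lines.append(f"n_minima {p.n_minima}")
        for r, e in zip(p.distance_grid, p.energy):
            lines.append(f"{r:.6f} {e:.6f}")
    hb = config.hb
    lines += [
        "[hbond]",
        f"well_depth {hb.well_depth:.6f}",
        f"equilibrium_short {hb.equilibrium_short:.6f}",
        f"equilibrium_long {hb.equilibrium_long:.6f}",
        f"angular_exponent {hb.angular_exponent:.6f}",
        f"cutoff {hb.cutoff:.6f}",
        "[vdw]",
        "# role radius(A) depth(kcal/mol)",
    ]
    for role in sorted(config.vdw):
        radius, depth = config.vdw[role]
        lines.append(f"{_NAME_BY_ROLE[role]} {radius:.6f} {depth:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_forcefield(path) -> ForceFieldConfig:
    """Read a parameter file written by :func:`save_forcefield`."""
    with open(path) as fh:
        text = fh.read()
    return _parse_forcefield(text)


def _parse_forcefield(text: str) -> ForceFieldConfig:
    section = None
    eps = np.zeros((N_TYPES, N_TYPES))
    attractive = np.zeros((N_TYPES, N_TYPES), dtype=bool)
    r0 = np.zeros((N_TYPES, N_TYPES))
    provenance = ""
    cutoff: float | None = 16.0
    sb_raw: dict[str, dict] = {}
    hb_raw: dict[str, float] = {}
    vdw: dict[int, tuple[float, float]] = {}
    current_sb = None
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("# provenance:"):
            provenance = line.split(":", 1)[1].strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            section = line.strip("[]")
            if section.startswith("saltbridge:"):
                current_sb = section.split(":", 1)[1]
                sb_raw[current_sb] = {"grid": [], "energy": [], "n_minima": 1}
            continue
        parts = line.split()
        if section == "meta":
            if parts[0] == "cutoff":
                cutoff = None if parts[1] == "none" else float(parts[1])
        elif section == "pairs":
            a, b = TYPE_INDEX[parts[0]], TYPE_INDEX[parts[1]]
            eps[a, b] = eps[b, a] = float(parts[2])
            attractive[a, b] = attractive[b, a] = parts[3] == "attractive"
            r0[a, b] = r0[b, a] = float(parts[4])
        elif section and section.startswith("saltbridge:"):
            if parts[0] == "n_minima":
                sb_raw[current_sb]["n_minima"] = int(parts[1])
            else:
                sb_raw[current_sb]["grid"].append(float(parts[0]))
                sb_raw[current_sb]["energy"].append(float(parts[1]))
        elif section == "hbond":
            hb_raw[parts[0]] = float(parts[1])
        elif section == "vdw":
            vdw[_ROLE_BY_NAME[parts[0]]] = (float(parts[1]), float(parts[2]))
    profiles = {
        key: SaltBridgeProfile(key, np.asarray(d["grid"]), np.asarray(d["energy"]),
                               d["n_minima"])
        for key, d in sb_raw.items()
    }
    table = PairParameterTable(eps=eps, attractive=attractive, r0=r0,
                               provenance=provenance)
    return ForceFieldConfig(pair_table=table, sb_profiles=profiles,
                            hb=HBondParams(**hb_raw) if hb_raw else HBondParams(),
                            vdw=vdw or dict(DEFAULT_VDW), cutoff=cutoff)


def load_default() -> ForceFieldConfig:
    """Load the parameter file shipped with the package."""
    ref = resources.files("opepdock").joinpath("data/default.ff")
    return _parse_forcefield(ref.read_text())
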