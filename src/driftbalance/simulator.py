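"""Desk-scale agent-based biofilm simulator.

Spherical heterotrophic cells sit on the floor of a cuboid domain that is
periodic in X/Y, closed at the substratum (z = 0) and fed by a fixed bulk
substrate concentration at the top boundary.  Cells grow by Monod kinetics on
the local substrate concentration, divide with a random biomass split
(U(0.4, 0.6)) in a random direction once they pass a diameter threshold, and
are relaxed apart ("shoving") after growth and division.  The substrate field
is the steady state of a diffusion-reaction balance recomputed every growth
step (quasi-static transport: diffusion relaxes orders of magnitude faster
than growth at micrometre scales).

All randomness comes from a single Park-Miller stream per run, so a run is a
deterministic function of ``(config, seed)``.  With identical kinetics the
only forces separating lineages are the random splits and directions --
ecological drift -- while a kinetic override for one lineage adds a
deterministic selective advantage on top.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numba
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .rng import ParkMiller

logger = logging.getLogger(__name__)

__all__ = [
    "Kinetics",
    "Cell",
    "LoserOverride",
    "SimulationConfig",
    "SubstrateField",
    "Population",
    "RunResult",
    "ConfigError",
    "SolverError",
    "monod_rate",
    "mass_to_diameter",
    "diameter_to_mass",
    "init_population",
    "divide",
    "relax",
    "solve_substrate",
    "grow_step",
    "run",
    "run_to_rows",
    "RUN_TABLE_COLUMNS",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class SolverError(RuntimeError):
    """Substrate solver failed to converge."""


# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Kinetics:
    """Monod growth parameters.

    mu_max : maximum specific growth rate (1/h)
    K_s    : half-saturation constant (kg m^-3)
    yield_ : biomass produced per substrate consumed (kg/kg)
    """

    mu_max: float
    K_s: float
    yield_: float

    def __post_init__(self):
        for name in ("mu_max", "K_s", "yield_"):
            v = getattr(self, name)
            if not (v > 0):
                raise ConfigError(f"Kinetics.{name} must be > 0, got {v}")

    def altered(self, dKs_pct: float = 0.0, dmu_pct: float = 0.0) -> "Kinetics":
        """Kinetics with K_s and mu_max scaled by the given percent changes."""
        if dKs_pct <= -100:
            raise ConfigError(f"dKs_pct must be > -100, got {dKs_pct}")
        if dmu_pct <= -100:
            raise ConfigError(f"dmu_pct must be > -100, got {dmu_pct}")
        return Kinetics(
            mu_max=self.mu_max * (1.0 + dmu_pct / 100.0),
            K_s=self.K_s * (1.0 + dKs_pct / 100.0),
            yield_=self.yield_,
        )


#: baseline kinetics: mu_max 1 1/h, K_s 3.5e-5 kg m^-3, yield 0.61 kg/kg
BASE_KINETICS = Kinetics(mu_max=1.0, K_s=3.5e-5, yield_=0.61)

#: dry biomass density (kg m^-3) relating mass and diameter, m = rho*pi*d^3/6.
#: A convention, configurable in one place; co-scaling it with the bulk
#: concentration and K_s is an exact symmetry of the model (uptake scales
#: with mass, so scaling the density alone does change the field).
DEFAULT_DENSITY = 150.0


def mass_to_diameter(mass: float | np.ndarray, density: float = DEFAULT_DENSITY):
    """Sphere diameter from biomass under the constant-density convention."""
    return np.cbrt(6.0 * np.asarray(mass) / (math.pi * density))


def diameter_to_mass(diameter: float | np.ndarray, density: float = DEFAULT_DENSITY):
    """Biomass from sphere diameter under the constant-density convention."""
    d = np.asarray(diameter)
    return density * math.pi * d**3 / 6.0


@dataclass
class Cell:
    """A single spherical cell.

    ``diameter`` is always kept consistent with ``mass`` through the
    constant-density sphere convention.
    """

    position: np.ndarray
    mass: float
    lineage_id: int
    kinetics: Kinetics
    density: float = DEFAULT_DENSITY

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.mass <= 0:
            raise ConfigError(f"cell mass must be > 0, got {self.mass}")
        if self.position.shape != (3,):
            raise ConfigError("cell position must be a 3-vector")
        if self.position[2] < 0:
            raise ConfigError("cell centre below the substratum (z < 0)")

    @property
    def diameter(self) -> float:
        return float(mass_to_diameter(self.mass, self.density))


@dataclass(frozen=True)
class LoserOverride:
    """Kinetic alteration applied to one lineage in a re-run."""

    lineage_id: int
    dKs_pct: float = 0.0
    dmu_pct: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """All physical, kinetic and design parameters of one run.

    The domain edge in X and Y is ``sqrt(n_initial) * spacing *
    initial_diameter`` so that founders sit on a uniformly spaced grid under
    the periodic wrap.  The Z (height) extent is fixed and the stop criterion
    is measured against the full cuboid volume.
    """

    n_initial: int = 9
    spacing: float = 5.0                    # in initial cell diameters
    initial_diameter: float = 1.0e-6        # m
    division_diameter: float = 1.36e-6      # m
    base_kinetics: Kinetics = BASE_KINETICS
    bulk_concentration: float = 1.0e-4      # kg m^-3, top boundary + initial field
    domain_height: float = 2.0e-4           # m
    stop_volume_fraction: float = 0.20
    seed: int = 1
    loser_override: Optional[LoserOverride] = None
    # numerical resolution knobs
    density: float = DEFAULT_DENSITY        # kg m^-3
    diffusivity: float = 3.6e-6             # m^2/h (1e-9 m^2/s, small solute in water)
    voxel_edge: float = 5.0e-6              # m, horizontal substrate voxel edge
    voxel_edge_z: float = 2.0e-6            # m, vertical edge; must resolve the
                                            # near-cell gradient or drift vanishes
    mu_dt_max: float = 0.1                  # max per-step relative mass change
    relax_tol: float = 1.0e-3               # overlap tolerance, fraction of radius sum
    relax_cap: int = 10_000                 # total relaxation iteration cap
    max_steps: int = 50_000
    substrate_tol: float = 1.0e-6           # Picard tolerance, fraction of bulk
    substrate_cap: int = 200

    def __post_init__(self):
        m = math.isqrt(self.n_initial)
        if m * m != self.n_initial:
            raise ConfigError(
                f"n_initial must be a perfect square, got {self.n_initial}"
            )
        if not (0 < self.stop_volume_fraction < 1):
            raise ConfigError("stop_volume_fraction must be in (0, 1)")
        if self.spacing <= 1:
            raise ConfigError("spacing must exceed one cell diameter")
        if self.initial_diameter <= 0 or self.division_diameter <= 0:
            raise ConfigError("diameters must be positive")
        if self.seed < 1:
            raise ConfigError("seed must be a positive integer")

    @property
    def domain_xy(self) -> float:
        return math.isqrt(self.n_initial) * self.spacing * self.initial_diameter

    @property
    def domain_volume(self) -> float:
        return self.domain_xy**2 * self.domain_height

    def kinetics_for_lineage(self, lineage_id: int) -> Kinetics:
        ov = self.loser_override
        if ov is not None and ov.lineage_id == lineage_id:
            return self.base_kinetics.altered(ov.dKs_pct, ov.dmu_pct)
        return self.base_kinetics


@dataclass
class SubstrateField:
    """Substrate concentration on a voxel grid.

    ``concentrations`` has shape (nx, ny, nz); the top layer (iz = nz-1) is
    held at the bulk value.  Voxel edges may differ per axis so the grid
    tiles the domain exactly.
    """

    concentrations: np.ndarray
    voxel_edges: tuple[float, float, float]
    bulk_concentration: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.concentrations.shape


@dataclass
class Population:
    """Structure-of-arrays cell container (one row per living cell)."""

    positions: np.ndarray          # (N, 3), m
    masses: np.ndarray             # (N,), kg
    lineages: np.ndarray           # (N,), int, in [1, n_initial]
    mu_max: np.ndarray             # (N,), 1/h
    K_s: np.ndarray                # (N,), kg m^-3
    yield_: float
    density: float = DEFAULT_DENSITY

    @property
    def n(self) -> int:
        return self.masses.size

    @property
    def diameters(self) -> np.ndarray:
        return mass_to_diameter(self.masses, self.density)

    @property
    def volumes(self) -> np.ndarray:
        return self.masses / self.density

    def lineage_biomass(self, n_lineages: int) -> np.ndarray:
        """Total biomass per lineage id 1..n_lineages."""
        return np.bincount(
            self.lineages, weights=self.masses, minlength=n_lineages + 1
        )[1:]

    def cell(self, i: int) -> Cell:
        return Cell(
            position=self.positions[i].copy(),
            mass=float(self.masses[i]),
            lineage_id=int(self.lineages[i]),
            kinetics=Kinetics(float(self.mu_max[i]), float(self.K_s[i]), self.yield_),
            density=self.density,
        )


@dataclass
class RunResult:
    """Final state summary of one run."""

    final_fractions: np.ndarray     # indexed by lineage-1, sums to 1
    loser_id: int
    status: list[str]               # per-lineage classification label
    seed: int
    config: SimulationConfig
    n_steps: int
    total_biomass: float
    stop_volume_fraction: float     # realised biomass volume fraction at stop

    def fraction(self, lineage_id: int) -> float:
        return float(self.final_fractions[lineage_id - 1])


RUN_TABLE_COLUMNS = [
    "run_id", "seed", "n_initial", "spacing", "dKs_pct", "dmu_pct",
    "lineage_id", "final_fraction", "is_loser", "status",
]


def run_to_rows(result: RunResult, run_id: str) -> list[dict]:
    """Long-form run-table rows (one per lineage), the contract consumed by
    all downstream stages."""
    cfg = result.config
    ov = cfg.loser_override
    rows = []
    for lid in range(1, cfg.n_initial + 1):
        rows.append({
            "run_id": run_id,
            "seed": result.seed,
            "n_initial": cfg.n_initial,
            "spacing": cfg.spacing,
            "dKs_pct": ov.dKs_pct if ov is not None else 0.0,
            "dmu_pct": ov.dmu_pct if ov is not None else 0.0,
            "lineage_id": lid,
            "final_fraction": result.fraction(lid),
            "is_loser": lid == result.loser_id,
            "status": result.status[lid - 1],
        })
    return rows


# --------------------------------------------------------------------------
# growth kinetics
# --------------------------------------------------------------------------

def monod_rate(kinetics: Kinetics, S) -> float | np.ndarray:
    """Monod specific growth rate mu = mu_max * S / (K_s + S), in 1/h.

    Bounded in [0, mu_max) and monotone nondecreasing in S.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be >= 0")
    out = kinetics.mu_max * S / (kinetics.K_s + S)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# initialisation
# --------------------------------------------------------------------------

def init_population(config: SimulationConfig) -> tuple[Population, SubstrateField]:
    """Founders on an evenly spaced MxM grid at the base, field at bulk.

    Nearest-neighbour centre distance is ``spacing * initial_diameter`` both
    inside the grid and across the periodic edges.  Lineage ids 1..N follow
    row-major grid order.
    """
    m = math.isqrt(config.n_initial)
    if m * m != config.n_initial:
        raise ConfigError(f"n_initial must be a perfect square, got {config.n_initial}")
    pitch = config.spacing * config.initial_diameter
    r0 = config.initial_diameter / 2.0
    pos = np.zeros((config.n_initial, 3))
    k = 0
    for i in range(m):
        for j in range(m):
            pos[k] = (i * pitch, j * pitch, r0)
            k += 1
    mass0 = float(diameter_to_mass(config.initial_diameter, config.density))
    masses = np.full(config.n_initial, mass0)
    lineages = np.arange(1, config.n_initial + 1, dtype=np.int64)
    mu = np.empty(config.n_initial)
    ks = np.empty(config.n_initial)
    for idx, lid in enumerate(lineages):
        kin = config.kinetics_for_lineage(int(lid))
        mu[idx] = kin.mu_max
        ks[idx] = kin.K_s
    popn = Population(
        positions=pos, masses=masses, lineages=lineages,
        mu_max=mu, K_s=ks, yield_=config.base_kinetics.yield_,
        density=config.density,
    )

    L = config.domain_xy
    nx = max(1, round(L / config.voxel_edge))
    nz = max(2, round(config.domain_height / config.voxel_edge_z))
    edges = (L / nx, L / nx, config.domain_height / nz)
    conc = np.full((nx, nx, nz), config.bulk_concentration)
    fld = SubstrateField(conc, edges, config.bulk_concentration)
    return popn, fld


# --------------------------------------------------------------------------
# division
# --------------------------------------------------------------------------

def divide(cell: Cell, rng: ParkMiller,
           division_diameter: float = 1.36e-6) -> tuple[Cell, Cell]:
    """Split a cell above the division threshold into two daughters.

    The first daughter receives a uniformly random 40-60% of the parent
    biomass, the second the remainder (masses conserve exactly).  Both
    daughters inherit the parent's lineage and kinetics.  Their centres are
    placed tangent to each other along a direction uniform on the unit
    sphere, centred on the parent's position.

    Draw order from the Park-Miller stream: split fraction, then the two
    direction deviates.
    """
    if cell.diameter <= division_diameter:
        raise ValueError(
            f"cell diameter {cell.diameter:.3e} m is not above the division "
            f"threshold {division_diameter:.3e} m"
        )
    f = rng.split_fraction()
    direction = np.array(rng.unit_vector())
    m1 = f * cell.mass
    m2 = cell.mass - m1
    d1 = float(mass_to_diameter(m1, cell.density))
    d2 = float(mass_to_diameter(m2, cell.density))
    half_sep = (d1 + d2) / 4.0  # tangency: centre distance = r1 + r2
    p1 = cell.position + half_sep * direction
    p2 = cell.position - half_sep * direction
    # keep daughters above the substratum; X/Y wrapping is the caller's job
    p1[2] = max(p1[2], d1 / 2.0)
    p2[2] = max(p2[2], d2 / 2.0)
    kin = cell.kinetics
    return (
        Cell(p1, m1, cell.lineage_id, kin, cell.density),
        Cell(p2, m2, cell.lineage_id, kin, cell.density),
    )


# --------------------------------------------------------------------------
# mechanical relaxation ("shoving")
# --------------------------------------------------------------------------

@numba.njit(cache=False)
def _find_contacts(pos, radii, Lx, Ly, search, margin):
    """Cell-list neighbour search (periodic X/Y, open Z).

    Returns (i, j, rsum) for all pairs closer than ``search`` whose overlap
    exceeds ``-margin * rsum`` (near-contact), plus the maximum relative
    overlap over every pair within ``search`` (the convergence measure).
    Deterministic: pairs are enumerated in bin order.
    """
    n = pos.shape[0]
    nbx = max(1, int(Lx / search))
    nby = max(1, int(Ly / search))
    bx = Lx / nbx
    by = Ly / nby
    zmax = 0.0
    for a in range(n):
        if pos[a, 2] > zmax:
            zmax = pos[a, 2]
    nbz = int(zmax / search) + 1
    nbins = nbx * nby * nbz

    binid = np.empty(n, dtype=np.int64)
    counts = np.zeros(nbins + 1, dtype=np.int64)
    for a in range(n):
        ix = int(pos[a, 0] / bx)
        if ix >= nbx:
            ix = nbx - 1
        iy = int(pos[a, 1] / by)
        if iy >= nby:
            iy = nby - 1
        iz = int(pos[a, 2] / search)
        if iz >= nbz:
            iz = nbz - 1
        b = (ix * nby + iy) * nbz + iz
        binid[a] = b
        counts[b + 1] += 1
    for b in range(nbins):
        counts[b + 1] += counts[b]
    order = np.empty(n, dtype=np.int64)
    fill = counts[:nbins].copy()
    for a in range(n):
        order[fill[binid[a]]] = a
        fill[binid[a]] += 1

    # single pass into a generously sized buffer (dense equal-sphere packing
    # tops out near 12 contacts per cell; the margin adds a few more)
    cap_pairs = 24 * n + 64
    ii = np.empty(cap_pairs, dtype=np.int64)
    jj = np.empty(cap_pairs, dtype=np.int64)
    rr = np.empty(cap_pairs, dtype=np.float64)
    neigh = np.empty(27, dtype=np.int64)
    # bin aliasing under the periodic wrap only happens on tiny grids
    need_dedup = nbx < 3 or nby < 3
    max_rel = 0.0
    k = 0
    s2 = search * search
    for a in range(n):
        bix = binid[a] // (nby * nbz)
        biy = (binid[a] // nbz) % nby
        biz = binid[a] % nbz
        nneigh = 0
        for ox in range(-1, 2):
            cx_ = (bix + ox) % nbx
            for oy in range(-1, 2):
                cy_ = (biy + oy) % nby
                for oz in range(-1, 2):
                    cz_ = biz + oz
                    if cz_ < 0 or cz_ >= nbz:
                        continue
                    nb = (cx_ * nby + cy_) * nbz + cz_
                    if need_dedup:
                        dup = False
                        for q in range(nneigh):
                            if neigh[q] == nb:
                                dup = True
                                break
                        if dup:
                            continue
                        neigh[nneigh] = nb
                        nneigh += 1
                    for s in range(counts[nb], counts[nb + 1]):
                        b2 = order[s]
                        if b2 <= a:
                            continue
                        dx = pos[a, 0] - pos[b2, 0]
                        dy = pos[a, 1] - pos[b2, 1]
                        dz = pos[a, 2] - pos[b2, 2]
                        dx -= Lx * np.floor(dx / Lx + 0.5)
                        dy -= Ly * np.floor(dy / Ly + 0.5)
                        dist2 = dx * dx + dy * dy + dz * dz
                        if dist2 >= s2:
                            continue
                        rs = radii[a] + radii[b2]
                        dist = np.sqrt(dist2)
                        rel = (rs - dist) / rs
                        if rel > max_rel:
                            max_rel = rel
                        if dist < rs * (1.0 + margin) and k < cap_pairs:
                            ii[k] = a
                            jj[k] = b2
                            rr[k] = rs
                            k += 1
    return ii[:k], jj[:k], rr[:k], max_rel


@numba.njit(cache=False)
def _relax_sweeps(pos, radii, i, j, rsum, Lx, Ly, height, tol, damping,
                  max_sweeps):
    """Gauss-Seidel overlap projection over a fixed pair list.

    Pairs are processed in a fixed order with immediate position updates
    (deterministic, and overlap corrections propagate within a sweep).
    Returns the number of sweeps performed; stops early once the largest
    relative overlap on the list is below ``tol``.
    """
    npairs = i.size
    sweeps = 0
    for _s in range(max_sweeps):
        worst = 0.0
        for k in range(npairs):
            a, b = i[k], j[k]
            dx = pos[a, 0] - pos[b, 0]
            dy = pos[a, 1] - pos[b, 1]
            dz = pos[a, 2] - pos[b, 2]
            dx -= Lx * np.floor(dx / Lx + 0.5)
            dy -= Ly * np.floor(dy / Ly + 0.5)
            dist = np.sqrt(dx * dx + dy * dy + dz * dz)
            overlap = rsum[k] - dist
            rel = overlap / rsum[k]
            if rel > worst:
                worst = rel
            if overlap > 0.0:
                if dist < 1e-18:
                    # coincident centres: deterministic fallback direction
                    dx, dy, dz = 1.0, 0.0, 0.0
                    dist = 1.0
                push = 0.5 * damping * overlap / dist
                px, py, pz = push * dx, push * dy, push * dz
                pos[a, 0] += px
                pos[a, 1] += py
                pos[a, 2] += pz
                pos[b, 0] -= px
                pos[b, 1] -= py
                pos[b, 2] -= pz
                # hard substratum below, lid far above
                za = pos[a, 2]
                if za < radii[a]:
                    pos[a, 2] = radii[a]
                elif za > height - radii[a]:
                    pos[a, 2] = height - radii[a]
                zb = pos[b, 2]
                if zb < radii[b]:
                    pos[b, 2] = radii[b]
                elif zb > height - radii[b]:
                    pos[b, 2] = height - radii[b]
        sweeps += 1
        if worst < tol:
            break
    return sweeps


def relax(positions: np.ndarray, diameters: np.ndarray, Lx: float, Ly: float,
          height: float, tol: float = 1.0e-3, cap: int = 10_000,
          damping: float = 0.8) -> np.ndarray:
    """Push overlapping spheres apart until the residual overlap is small.

    Overlapping pairs are displaced along their centre line, half the
    (damped) overlap each, with minimum-image wrapping in X/Y and the centre
    height clamped to [radius, height - radius] (hard substratum below, lid
    far above).  Convergence: the maximum overlap, relative to the pair's
    radius sum, is below ``tol`` on a freshly rebuilt neighbour list.  If the
    iteration cap is hit a warning is logged and the current state returned.
    """
    pos = np.array(positions, dtype=float)
    n = pos.shape[0]
    if n <= 1:
        return pos
    radii = np.ascontiguousarray(diameters / 2.0)
    pos[:, 0] %= Lx
    pos[:, 1] %= Ly
    np.clip(pos[:, 2], radii, height - radii, out=pos[:, 2])
    dmax = float(diameters.max())
    search = 1.3 * dmax
    iters = 0
    refresh = 30
    while iters < cap:
        # near-contact pair list (margin: per-sweep movements are much
        # smaller, and the rebuild catches anything pushed further)
        i, j, rsum, max_rel = _find_contacts(pos, radii, Lx, Ly, search, 0.1)
        if max_rel < tol:
            return pos  # converged on a fresh neighbour list
        done = _relax_sweeps(
            pos, radii, i, j, rsum,
            Lx, Ly, height, tol, damping, min(refresh, cap - iters),
        )
        iters += int(done)
        pos[:, 0] %= Lx
        pos[:, 1] %= Ly
    logger.warning("relax: iteration cap %d reached; residual overlap remains", cap)
    return pos


# --------------------------------------------------------------------------
# substrate diffusion-reaction steady state
# --------------------------------------------------------------------------

def _assemble_laplacian(shape: tuple[int, int, int],
                        edges: tuple[float, float, float],
                        diffusivity: float,
                        far_layers: int = 1) -> sp.csr_matrix:
    """-D * discrete Laplacian with periodic X/Y and zero-flux bottom.

    The top layer of the (possibly truncated) grid couples to the fixed bulk
    value through ``far_layers`` substrate-free layers above it, as a single
    implicit conductance ``cz / far_layers`` (exact, since the steady state
    is linear where there are no sinks).  The matching right-hand-side
    contribution ``(cz / far_layers) * bulk`` is added by the solver.
    ``far_layers=1`` reduces to the plain Dirichlet neighbour."""
    nx, ny, nz = shape
    hx, hy, hz = edges
    n = nx * ny * nz
    cx, cy, cz = diffusivity / hx**2, diffusivity / hy**2, diffusivity / hz**2

    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    p = ((ix * ny + iy) * nz + iz).ravel()
    ix, iy, iz = ix.ravel(), iy.ravel(), iz.ravel()
    all_ = np.ones(n, dtype=bool)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    def add_neighbour(mask, nb_index, coeff):
        rows.append(p[mask])
        cols.append(nb_index[mask])
        vals.append(np.full(np.count_nonzero(mask), -coeff))
        diag[p[mask]] += coeff

    if nx > 1:
        add_neighbour(all_, (((ix - 1) % nx) * ny + iy) * nz + iz, cx)
        add_neighbour(all_, (((ix + 1) % nx) * ny + iy) * nz + iz, cx)
    if ny > 1:
        add_neighbour(all_, (ix * ny + (iy - 1) % ny) * nz + iz, cy)
        add_neighbour(all_, (ix * ny + (iy + 1) % ny) * nz + iz, cy)
    add_neighbour(iz > 0, p - 1, cz)          # below (zero-flux mirror at z=0)
    add_neighbour(iz < nz - 1, p + 1, cz)     # above, inside the grid
    diag[p[iz == nz - 1]] += cz / far_layers  # implicit far-field coupling
    rows.append(p)
    cols.append(p)
    vals.append(diag[p])
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def _voxel_index(popn: Population, fld: SubstrateField) -> np.ndarray:
    nx, ny, nz = fld.shape
    hx, hy, hz = fld.voxel_edges
    ix = np.floor(popn.positions[:, 0] / hx).astype(np.int64) % nx
    iy = np.floor(popn.positions[:, 1] / hy).astype(np.int64) % ny
    iz = np.clip(np.floor(popn.positions[:, 2] / hz).astype(np.int64), 0, nz - 1)
    return (ix * ny + iy) * nz + iz


def solve_substrate(fld: SubstrateField, popn: Population,
                    config: SimulationConfig, dt: float,
                    laplacian_cache: Optional[dict] = None,
                    diagnostics: Optional[dict] = None) -> SubstrateField:
    """Steady-state substrate field for the current biomass distribution.

    Solves ``D * laplacian(S) = sum of uptake`` with the Monod sink
    linearised semi-implicitly (Picard iteration), which keeps the discrete
    operator an M-matrix and hence S nonnegative and bounded by the bulk
    value.  Each cell's uptake, ``m * (exp(mu*dt) - 1) / (yield * dt)``, is
    apportioned to its voxel; the exponential factor makes the reaction
    term's consumption equal the biomass gained over the step divided by
    yield, so growth and uptake stay in closed balance.

    Above the highest cell the steady state is exactly linear in z, so the
    linear system is solved on a grid truncated a few layers above the
    biomass, with the truncation layer held at the analytically continued
    value (updated with the flux each Picard iteration).  The returned field
    is reconstructed on the full grid.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    nx, ny, nz = fld.shape
    hx, hy, hz = fld.voxel_edges
    bulk = fld.bulk_concentration
    if popn.n == 0:
        return SubstrateField(np.full(fld.shape, bulk), fld.voxel_edges, bulk)

    # truncate a few layers above the biomass (all sinks must stay below);
    # the top truncated layer couples implicitly to the bulk value through
    # the remaining substrate-free layers
    top_cell_layer = int(np.max(popn.positions[:, 2]) / hz)
    nz_t = min(nz - 1, top_cell_layer + 4)
    far = nz - nz_t
    if laplacian_cache is not None and nz_t in laplacian_cache:
        laplacian = laplacian_cache[nz_t]
    else:
        laplacian = _assemble_laplacian((nx, ny, nz_t), (hx, hy, hz),
                                        config.diffusivity, far_layers=far)
        if laplacian_cache is not None:
            laplacian_cache[nz_t] = laplacian

    nvox = nx * ny * nz_t
    cz = config.diffusivity / hz**2
    S = fld.concentrations[:, :, :nz_t].reshape(-1).copy()
    top = np.arange(nvox).reshape(nx, ny, nz_t)[:, :, nz_t - 1].ravel()
    rhs = np.zeros(nvox)
    rhs[top] = (cz / far) * bulk
    vox = _voxel_index(popn, fld)
    # re-index onto the truncated grid (cells all lie below the truncation)
    vox = (vox // nz) * nz_t + np.minimum(vox % nz, nz_t - 1)
    vvol = hx * hy * hz
    for _it in range(config.substrate_cap):
        S_cell = S[vox]
        mu = popn.mu_max * S_cell / (popn.K_s + S_cell)
        # exponential-growth correction (exp(mu dt)-1)/(mu dt), -> 1 as mu->0
        x = mu * dt
        gfac = np.where(x > 1e-12, np.expm1(x) / np.maximum(x, 1e-300), 1.0)
        # semi-implicit sink: rate_i = coeff_i * S(vox_i)
        coeff = popn.mu_max * popn.masses * gfac / (popn.yield_ * (popn.K_s + S_cell))
        sink = np.bincount(vox, weights=coeff / vvol, minlength=nvox)
        A = laplacian + sp.diags(sink)
        S_new = spla.spsolve(A.tocsc(), rhs)
        delta = np.max(np.abs(S_new - S)) / bulk
        S = S_new
        if delta < config.substrate_tol:
            S = np.clip(S, 0.0, bulk)
            if diagnostics is not None:
                # substrate consumed per unit time by the converged reaction
                # term (kg/h); times dt it must balance biomass gain / yield
                diagnostics["reaction_rate"] = float(np.dot(coeff, S[vox]))
            full = np.empty(fld.shape)
            full[:, :, :nz_t] = S.reshape(nx, ny, nz_t)
            # linear continuation per column up to the bulk boundary layer
            layers = np.arange(nz_t, nz)
            frac = (layers - (nz_t - 1)) / far
            s_t = full[:, :, nz_t - 1]
            full[:, :, nz_t:] = (
                s_t[:, :, None] + (bulk - s_t)[:, :, None] * frac[None, None, :]
            )
            return SubstrateField(full, fld.voxel_edges, bulk)
    raise SolverError(
        f"substrate Picard iteration did not converge in {config.substrate_cap} "
        f"iterations (last relative change {delta:.2e})"
    )


# --------------------------------------------------------------------------
# growth step
# --------------------------------------------------------------------------

def grow_step(popn: Population, fld: SubstrateField, dt: float,
              rng: ParkMiller, config: SimulationConfig) -> Population:
    """One growth step: exponential mass update, divisions, relaxation.

    Each cell's mass is multiplied by ``exp(mu * dt)`` with mu evaluated by
    Monod kinetics at its voxel's substrate concentration.  Cells whose
    diameter then exceeds the division threshold divide (in ascending array
    order, so the random-draw order is reproducible), and the whole
    population is mechanically relaxed.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0 or popn.n == 0:
        return popn
    vox = _voxel_index(popn, fld)
    S_cell = fld.concentrations.reshape(-1)[vox]
    mu = popn.mu_max * S_cell / (popn.K_s + S_cell)
    popn.masses = popn.masses * np.exp(mu * dt)

    # divisions (no cascading possible while mu*dt <= ~0.1, but loop anyway)
    positions = [popn.positions]
    while True:
        diam = popn.diameters
        above = np.nonzero(diam > config.division_diameter)[0]
        if above.size == 0:
            break
        new_pos, new_mass, new_lin, new_mu, new_ks = [], [], [], [], []
        for i in above:
            parent = popn.cell(int(i))
            d1, d2 = divide(parent, rng, config.division_diameter)
            popn.positions[i] = d1.position
            popn.masses[i] = d1.mass
            new_pos.append(d2.position)
            new_mass.append(d2.mass)
            new_lin.append(d2.lineage_id)
            new_mu.append(d2.kinetics.mu_max)
            new_ks.append(d2.kinetics.K_s)
        popn.positions = np.vstack([popn.positions, np.array(new_pos)])
        popn.masses = np.concatenate([popn.masses, new_mass])
        popn.lineages = np.concatenate([popn.lineages, np.array(new_lin, dtype=np.int64)])
        popn.mu_max = np.concatenate([popn.mu_max, new_mu])
        popn.K_s = np.concatenate([popn.K_s, new_ks])

    L = config.domain_xy
    popn.positions[:, 0] %= L
    popn.positions[:, 1] %= L
    popn.positions = relax(
        popn.positions, popn.diameters, L, L, config.domain_height,
        tol=config.relax_tol, cap=config.relax_cap,
    )
    return popn


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def run(config: SimulationConfig, diagnostics: Optional[dict] = None) -> RunResult:
    """Run one simulation to the stop volume fraction.

    Alternates the quasi-static substrate solve with a growth step (step
    size adapted so the fastest-growing cell's relative mass change stays at
    ``mu_dt_max``) until the biomass occupies ``stop_volume_fraction`` of
    the cuboid.  Bit-identical output for identical ``(config, seed)``.

    If ``diagnostics`` is supplied, per-step biomass gain and reaction-term
    substrate consumption are appended (for mass-balance checks).
    """
    from . import lineage_metrics  # deferred: avoids a hard cycle

    rng = ParkMiller(config.seed)
    popn, fld = init_population(config)
    laplacian_cache: dict = {}
    target = config.stop_volume_fraction * config.domain_volume
    mu_prev = np.full(popn.n, config.base_kinetics.mu_max)
    if config.loser_override is not None:
        mu_prev = popn.mu_max.copy()

    n_steps = 0
    vol = float(popn.volumes.sum())
    while vol < target:
        if n_steps >= config.max_steps:
            raise RuntimeError(
                f"step cap {config.max_steps} exceeded at biomass volume "
                f"fraction {vol / config.domain_volume:.4f} "
                f"(target {config.stop_volume_fraction})"
            )
        mu_top = float(np.max(mu_prev)) if mu_prev.size else config.base_kinetics.mu_max
        dt = config.mu_dt_max / max(mu_top, 1e-6)
        step_diag = {} if diagnostics is not None else None
        fld = solve_substrate(fld, popn, config, dt, laplacian_cache,
                              diagnostics=step_diag)
        mass_before = float(popn.masses.sum())
        popn = grow_step(popn, fld, dt, rng, config)
        mass_after = float(popn.masses.sum())
        vox = _voxel_index(popn, fld)
        S_cell = fld.concentrations.reshape(-1)[vox]
        mu_prev = popn.mu_max * S_cell / (popn.K_s + S_cell)
        if diagnostics is not None:
            diagnostics.setdefault("delta_biomass", []).append(mass_after - mass_before)
            diagnostics.setdefault("substrate_consumed", []).append(
                step_diag["reaction_rate"] * dt
            )
            diagnostics.setdefault("n_cells", []).append(popn.n)
        vol = float(popn.volumes.sum())
        n_steps += 1

    biomass = popn.lineage_biomass(config.n_initial)
    total = float(biomass.sum())
    fractions = biomass / total
    loser = int(np.argmin(fractions)) + 1  # argmin takes the lowest index on ties
    x_e = lineage_metrics.expected_abundance(total, config.n_initial)
    status = [lineage_metrics.classify(float(b), x_e) for b in biomass]
    logger.info(
        "run seed=%d n=%d spacing=%g: %d steps, %d cells, stop fraction %.4f",
        config.seed, config.n_initial, config.spacing, n_steps, popn.n,
        vol / config.domain_volume,
    )
    return RunResult(
        final_fractions=fractions,
        loser_id=loser,
        status=status,
        seed=config.seed,
        config=config,
        n_steps=n_steps,
        total_biomass=total,
        stop_volume_fraction=vol / config.domain_volume,
    )
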