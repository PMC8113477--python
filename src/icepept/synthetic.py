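"""Synthetic systems with known ground truth.

Everything the analysis stack consumes can be generated here: proton-
disordered hexagonal-ice (Ih) lattices, random liquid boxes, scripted
ice-growth trajectories with a binding probe, conformer ensembles with a
known energy/RMSD structure, and Voronoi grain maps.  The trajectories are
kinematic (scripted), not physical MD: the point is that every generated
quantity — front position, growth rate, binding time, torsion schedule,
grain areas — is known exactly, so the analyses can be validated by
ground-truth recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import min_image, place_fourth_atom

# ideal hexagonal-ice lattice constants, Å (standard ice Ih near 250 K)
DEFAULT_A = 4.50
DEFAULT_C = 7.34
OH_BOND = 0.9572          # covalent O–H length, Å
HOH_ANGLE = 104.52        # degrees
LIQUID_DENSITY = 0.0334   # molecules / Å^3 (≈ 1 g/cm³ water)

# ideal lonsdaleite (hexagonal diamond) fractional coordinates; z = 1/16
# makes all four bonds exactly equal when c/a = sqrt(8/3)
_HEX_FRACTIONAL = (
    (1 / 3, 2 / 3, 1 / 16),
    (2 / 3, 1 / 3, 9 / 16),
    (2 / 3, 1 / 3, 15 / 16),
    (1 / 3, 2 / 3, 7 / 16),
)


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# ice Ih lattice


@dataclass
class IceLattice:
    """Proton-disordered ice Ih on an orthorhombic box.

    ``bonds`` lists O–O hydrogen-bond pairs; ``h_owner`` maps each hydrogen
    to the oxygen that covalently owns it.  A valid lattice satisfies the
    Bernal–Fowler ice rules: every oxygen owns exactly two hydrogens and
    every O–O bond carries exactly one.
    """

    oxygen_positions: np.ndarray       # (N, 3) Å
    hydrogen_positions: np.ndarray     # (2N, 3) Å
    box: np.ndarray                    # (3,) Å
    bonds: np.ndarray                  # (M, 2) int, i <= j
    bond_shifts: np.ndarray            # (M, 3) int — periodic image of j per bond
    h_owner: np.ndarray                # (2N,) int — owning O index per H
    lattice_params: tuple[float, float] = (DEFAULT_A, DEFAULT_C)

    @property
    def n_molecules(self) -> int:
        return len(self.oxygen_positions)


def _ortho_cell_basis(a: float, c: float) -> tuple[np.ndarray, np.ndarray]:
    """Oxygen basis of the 8-molecule orthorhombic ice Ih cell (a, √3·a, c)."""
    cell = np.array([a, a * np.sqrt(3.0), c])
    pts = []
    for u, v, w in _HEX_FRACTIONAL:
        x = (u - v / 2.0) * a
        y = v * a * np.sqrt(3.0) / 2.0
        pts.append([x % cell[0], y % cell[1], w * c])
    pts = np.array(pts)
    pts = np.vstack([pts, pts + np.array([a / 2.0, a * np.sqrt(3.0) / 2.0, 0.0])])
    pts[:, :2] %= cell[:2]
    return pts, cell


def _replicate(basis: np.ndarray, cell: np.ndarray, n_cells) -> tuple[np.ndarray, np.ndarray]:
    nx, ny, nz = n_cells
    shifts = np.array([[i, j, k] for i in range(nx) for j in range(ny) for k in range(nz)],
                      dtype=float) * cell
    pos = (basis[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    return pos, cell * np.array([nx, ny, nz], dtype=float)


def _oo_bonds(oxygens: np.ndarray, box: np.ndarray, cutoff: float = 3.2
              ) -> tuple[np.ndarray, np.ndarray]:
    """Image-aware O–O hydrogen-bond list.

    Returns (pairs, shifts) where shifts give the periodic image of the
    second oxygen: in boxes smaller than twice the cutoff a pair can be
    bonded through two distinct images, and each image is its own bond.
    """
    n = len(oxygens)
    pairs, shifts = [], []
    shift_grid = np.array([[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1)
                           for k in (-1, 0, 1)])
    for i in range(n):
        d = oxygens[i + 1:] - oxygens[i]               # (n-i-1, 3)
        for s in shift_grid:
            dd = d + s * box
            close = np.flatnonzero(np.einsum("ij,ij->i", dd, dd) < cutoff**2)
            for c in close:
                pairs.append((i, i + 1 + c))
                shifts.append(s)
    return np.array(pairs, dtype=int), np.array(shifts, dtype=int)


def _assign_protons(n_oxygens: int, bonds: np.ndarray, rng: np.random.Generator,
                    budget: int = 1_000_000) -> np.ndarray:
    """Orient each O–O bond (who owns its hydrogen) so every O owns exactly 2.

    Random initial orientation followed by defect random walks: an oxygen
    owning more than two hydrogens hands one to a neighbour by flipping an
    outgoing bond; the surplus defect walks until it annihilates with a
    deficit.  Returns owner O index per bond.
    """
    m = len(bonds)
    owner = np.where(rng.random(m) < 0.5, bonds[:, 0], bonds[:, 1])
    own_count = np.bincount(owner, minlength=n_oxygens)
    # adjacency: bond indices per oxygen
    adj: list[list[int]] = [[] for _ in range(n_oxygens)]
    for bi, (i, j) in enumerate(bonds):
        adj[i].append(bi)
        adj[j].append(bi)
    steps = 0
    over = [int(i) for i in np.flatnonzero(own_count > 2)]
    while over:
        cur = over.pop()
        while own_count[cur] > 2:
            mine = [bi for bi in adj[cur] if owner[bi] == cur]
            bi = mine[rng.integers(len(mine))]
            i, j = bonds[bi]
            other = int(j if i == cur else i)
            owner[bi] = other
            own_count[cur] -= 1
            own_count[other] += 1
            steps += 1
            if steps > budget:
                raise GenerationError("proton-assignment repair exceeded its budget")
            cur = other
            if own_count[cur] <= 2:
                break
        over = [int(i) for i in np.flatnonzero(own_count > 2)]
    return owner


def _hydrogens_from_owners(oxygens: np.ndarray, bonds: np.ndarray,
                           shifts: np.ndarray, owner: np.ndarray,
                           box: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(oxygens)
    h_pos = np.empty((2 * n, 3))
    h_own = np.empty(2 * n, dtype=int)
    slot = np.zeros(n, dtype=int)
    for bi, (i, j) in enumerate(bonds):
        o = int(owner[bi])
        # displacement along this bond's specific periodic image
        if o == i:
            d = oxygens[j] + shifts[bi] * box - oxygens[i]
        else:
            d = oxygens[i] - shifts[bi] * box - oxygens[j]
        d /= np.linalg.norm(d)
        k = 2 * o + slot[o]
        h_pos[k] = oxygens[o] + OH_BOND * d
        h_own[k] = o
        slot[o] += 1
    if not (slot == 2).all():
        raise GenerationError("proton assignment left an oxygen without two hydrogens")
    return h_pos, h_own


def build_ice_ih(n_cells: tuple[int, int, int],
                 lattice_params: tuple[float, float] = (DEFAULT_A, DEFAULT_C),
                 seed: int = 0) -> IceLattice:
    """Build a periodic proton-disordered ice Ih lattice.

    The orthorhombic unit cell (a, √3·a, c) holds 8 molecules; the c axis is
    along z.  Protons are placed by randomized orientation repaired to
    Bernal–Fowler validity; deterministic for a fixed seed.
    """
    if any(n < 1 for n in n_cells):
        raise ValueError("n_cells components must be >= 1")
    a, c = lattice_params
    basis, cell = _ortho_cell_basis(a, c)
    oxygens, box = _replicate(basis, cell, n_cells)
    bonds, shifts = _oo_bonds(oxygens, box)
    rng = np.random.default_rng(seed)
    owner = _assign_protons(len(oxygens), bonds, rng)
    h_pos, h_own = _hydrogens_from_owners(oxygens, bonds, shifts, owner, box)
    return IceLattice(oxygens, h_pos, box, bonds, shifts, h_own, (a, c))


def bernal_fowler_violations(lattice: IceLattice,
                             covalent_cutoff: float = 1.2) -> int:
    """Audit the ice rules geometrically, independent of bookkeeping.

    Counts oxygens not owning exactly 2 hydrogens (hydrogen within the
    covalent cutoff of that oxygen) plus O–O bonds not carrying exactly 1
    hydrogen (a hydrogen covalent to one end and pointing along that bond's
    specific periodic image).
    """
    box = lattice.box
    o = lattice.oxygen_positions
    h = lattice.hydrogen_positions
    otree = cKDTree(np.mod(o, box), boxsize=box)
    # covalent owner of each H by geometry
    d, oidx = otree.query(np.mod(h, box), k=1)
    if (d > covalent_cutoff).any():
        return len(h)  # catastrophic: stray hydrogens
    own_count = np.bincount(oidx, minlength=len(o))
    violations = int(np.sum(own_count != 2))
    # bond directions per endpoint, resolved to each bond's own image
    bonds = lattice.bonds
    shifts = lattice.bond_shifts
    incident: dict[int, list[tuple[int, np.ndarray]]] = {}
    for bi, (i, j) in enumerate(bonds):
        d_ij = o[j] + shifts[bi] * box - o[i]
        incident.setdefault(int(i), []).append((bi, d_ij))
        incident.setdefault(int(j), []).append((bi, -d_ij))
    occupancy = np.zeros(len(bonds), dtype=int)
    for k in range(len(h)):
        i = int(oidx[k])
        vec = min_image(h[k] - o[i], box)
        best, best_cos = None, 0.0
        for bi, d_ij in incident.get(i, ()):
            cosang = float(np.dot(vec, d_ij)
                           / (np.linalg.norm(vec) * np.linalg.norm(d_ij)))
            if cosang > best_cos:
                best, best_cos = bi, cosang
        if best is None or best_cos < 0.8:
            violations += 1
            continue
        occupancy[best] += 1
    violations += int(np.sum(occupancy != 1))
    return violations


# ---------------------------------------------------------------------------
# frames


@dataclass
class FrameSet:
    """Multi-frame coordinate set with species labels and ground-truth metadata.

    ``species`` uses 'OW'/'HW' for water oxygen/hydrogen and free-form codes
    for probe atoms.  Coordinates are Å; times are ns.
    """

    coordinates: np.ndarray            # (F, A, 3)
    species: np.ndarray                # (A,) str
    box: np.ndarray                    # (3,)
    times: np.ndarray                  # (F,) ns
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.species = np.asarray(self.species)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[1] != len(self.species):
            raise ValueError("species length must match atom count")
        if len(self.times) != self.coordinates.shape[0]:
            raise ValueError("times length must match frame count")
        if (np.diff(self.times) < 0).any():
            raise ValueError("time stamps must be monotone")
        if (self.box <= 0).any():
            raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def indices(self, species: str) -> np.ndarray:
        return np.flatnonzero(self.species == species)

    def water_oxygens(self, frame: int) -> np.ndarray:
        return self.coordinates[frame][self.indices("OW")]


def _random_water_orientation(rng: np.random.Generator) -> np.ndarray:
    """Two O→H offset vectors of a randomly oriented rigid water."""
    half = np.radians(HOH_ANGLE / 2.0)
    local = np.array([
        [np.sin(half), 0.0, np.cos(half)],
        [-np.sin(half), 0.0, np.cos(half)],
    ]) * OH_BOND
    # random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return local @ q.T


def _rsa_positions(box: np.ndarray, n: int, min_sep: float,
                   rng: np.random.Generator, z_range=None,
                   fixed: np.ndarray | None = None,
                   budget_factor: int = 200) -> np.ndarray:
    """Random sequential insertion with a cell-grid overlap check."""
    if n == 0:
        return np.empty((0, 3))
    cell = max(min_sep, 1e-6)
    ncell = np.maximum(1, (box / cell).astype(int))
    grid: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def cell_of(p):
        return tuple((np.floor(p / box * ncell).astype(int)) % ncell)

    def ok(p):
        ci = np.array(cell_of(p))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    key = tuple((ci + [dx, dy, dz]) % ncell)
                    for q in grid.get(key, ()):
                        d = min_image(p - q, box)
                        if float(d @ d) < min_sep * min_sep:
                            return False
        return True

    def put(p):
        grid.setdefault(cell_of(p), []).append(p)

    if fixed is not None:
        for p in np.mod(fixed, box):
            put(p)
    placed = []
    tries = 0
    lo = 0.0 if z_range is None else z_range[0]
    hi = box[2] if z_range is None else z_range[1]
    while len(placed) < n:
        tries += 1
        if tries > budget_factor * n:
            raise GenerationError(
                f"random insertion failed after {tries} tries at separation "
                f"{min_sep} Å; lower the density or the separation")
        p = rng.uniform(0.0, box)
        p[2] = rng.uniform(lo, hi)
        if ok(p):
            put(p)
            placed.append(p)
    return np.array(placed)


def build_liquid_box(box, density: float = LIQUID_DENSITY,
                     min_separation: float = 2.6, seed: int = 0) -> FrameSet:
    """A single-frame random liquid box: sequential insertion of rigid waters
    with random orientations; count = round(density × volume)."""
    box = np.asarray(box, dtype=float)
    n = int(round(density * float(np.prod(box))))
    rng = np.random.default_rng(seed)
    opos = _rsa_positions(box, n, min_separation, rng)
    coords = []
    species = []
    for i in range(n):
        offs = _random_water_orientation(rng)
        coords.extend([opos[i], opos[i] + offs[0], opos[i] + offs[1]])
        species.extend(["OW", "HW", "HW"])
    coords = np.array(coords).reshape(1, -1, 3) if n else np.empty((1, 0, 3))
    return FrameSet(coords, np.array(species, dtype=object), box,
                    np.array([0.0]), {"density": density, "seed": seed})


# ---------------------------------------------------------------------------
# scripted growth/binding trajectory


@dataclass
class ScriptedTrajectoryParams:
    """Knobs of the scripted ice-growth + probe-binding trajectory.

    The ice front starts at ``slab_thickness`` and advances along +z at
    ``growth_rate`` Å/ns until ``t_bind`` (if set), then at
    ``growth_rate × post_bind_rate_factor`` — binding of an ice-growth
    inhibitor slows the front.  ``torsion_schedule`` maps time (ns) to the
    scripted C–S–S–C dihedral in degrees; by default the probe hops between
    the two disulfide conformer families (−85°/+85°).
    """

    box: tuple[float, float, float] = (13.5, 13.5, 80.0)
    slab_thickness: float = 10.0
    growth_rate: float = 0.5            # Å/ns
    frame_interval: float = 0.5         # ns
    n_frames: int = 160
    thermal_noise: float = 0.2          # σ, Å (liquid); ice gets σ/3
    t_bind: float | None = 60.0         # ns
    post_bind_rate_factor: float = 0.1
    contact_distance: float = -2.5      # signed probe–front offset once bound, Å
                                        # (negative = nestled into a cavity of the
                                        # rough surface, below the mean front plane)
    approach_distance: float = 15.0     # probe–front offset at t = 0, Å
    hover_distance: float = 6.5         # pre-binding standoff from the front, Å
    torsion_schedule: object = None     # callable t->deg, per-frame array, or None
    interface_roughness: float = 4.5    # growth-front roughness width w, Å:
                                        # a site freezes when the mean front
                                        # passes its z + U(-w/2, w/2)
    liquid_density: float = LIQUID_DENSITY
    min_separation: float = 2.6
    include_hydrogens: bool = True
    include_donor: bool = True
    lattice_params: tuple[float, float] = (DEFAULT_A, DEFAULT_C)
    seed: int = 0

    def __post_init__(self):
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        if self.thermal_noise < 0:
            raise ValueError("thermal_noise must be >= 0")
        span = self.frame_interval * (self.n_frames - 1)
        if self.t_bind is not None and not (0.0 <= self.t_bind <= span):
            raise ValueError(f"t_bind={self.t_bind} outside simulated span 0..{span} ns")

    def phi_at(self, t: np.ndarray) -> np.ndarray:
        sched = self.torsion_schedule
        if sched is None:
            # two conformer families: negative φ early, positive φ late
            span = self.frame_interval * (self.n_frames - 1)
            return np.where(t < span / 2.0, -85.0, 85.0)
        if callable(sched):
            return np.asarray([float(sched(x)) for x in np.atleast_1d(t)])
        arr = np.asarray(sched, dtype=float)
        if len(arr) != self.n_frames:
            raise ValueError("torsion_schedule array must have one value per frame")
        idx = np.clip(np.round(t / self.frame_interval).astype(int), 0, len(arr) - 1)
        return arr[idx]


def front_truth(params: ScriptedTrajectoryParams, t: np.ndarray) -> np.ndarray:
    """Scripted ground-truth front position z(t)."""
    t = np.asarray(t, dtype=float)
    v = params.growth_rate
    if params.t_bind is None:
        return params.slab_thickness + v * t
    pre = np.minimum(t, params.t_bind)
    post = np.maximum(t - params.t_bind, 0.0)
    return params.slab_thickness + v * pre + v * params.post_bind_rate_factor * post


def _prismatic_sites(box: np.ndarray, lattice_params) -> tuple[np.ndarray, np.ndarray]:
    """Ice Ih lattice sites with the c axis along x, so the face exposed
    along the growth axis z is a primary prismatic face.  The box is snapped
    to whole unit cells (returned) so the lattice tiles it periodically."""
    a, c = lattice_params
    basis, cell = _ortho_cell_basis(a, c)
    # permute axes: (x,y,z) -> (z,y,x) puts c along x and a along z
    basis = basis[:, [2, 1, 0]]
    cell = cell[[2, 1, 0]]
    n_cells = np.maximum(1, np.round(box / cell).astype(int))
    sites, actual = _replicate(basis, cell, tuple(n_cells))
    return sites, actual


def generate_trajectory(params: ScriptedTrajectoryParams) -> FrameSet:
    """Scripted ice-growth trajectory with a binding probe.

    Frame at time t has ice on lattice sites with z below the scripted front
    (jitter σ/3) and disordered liquid above (static random base positions,
    jitter σ).  Liquid molecules overtaken by the advancing front are
    snapped onto the engulfed lattice sites.  A methyl-carbon probe with a
    C–S–S–C chain (realizing the torsion schedule) approaches the front and
    sits at contact distance from ``t_bind`` onward.  Ground truth (front
    series, binding time, torsion schedule, per-frame ice counts) is
    embedded in ``metadata``.
    """
    requested_box = np.asarray(params.box, dtype=float)
    sites_all, box = _prismatic_sites(requested_box, params.lattice_params)
    rng = np.random.default_rng(params.seed)
    times = np.arange(params.n_frames) * params.frame_interval
    fronts = front_truth(params, times)
    n_frames = params.n_frames
    if fronts[-1] > box[2] - 5.0:
        keep = int(np.searchsorted(fronts, box[2] - 5.0))
        warnings.warn(
            f"ice front reaches the box top; truncating to {keep} frames")
        n_frames = max(keep, 2)
        times = times[:n_frames]
        fronts = fronts[:n_frames]

    sites = sites_all
    order = np.argsort(sites[:, 2], kind="stable")
    sites = sites[order]
    site_z = sites[:, 2]

    # kinetically rough growth front: site i freezes when the mean front
    # passes tau_i = z_i + U(-w/2, w/2); the initial surface obeys the same
    # rule, so the interface is in its rough steady state from frame 0
    w = params.interface_roughness
    n_lo = int(np.searchsorted(site_z, fronts[0] - w / 2, side="right"))
    n_hi = int(np.searchsorted(site_z, fronts[-1] + w / 2, side="right"))
    tau = np.full(n_hi, -np.inf)
    if n_hi > n_lo:
        tau[n_lo:] = site_z[n_lo:n_hi] + rng.uniform(-w / 2, w / 2, n_hi - n_lo)
    perm = tau <= fronts[0]                      # ice from frame 0
    feeder = np.flatnonzero(~perm & (tau <= fronts[-1]))
    feeder = feeder[np.argsort(tau[feeder], kind="stable")]
    perm_sites = sites[np.flatnonzero(perm)]
    n_perm = len(perm_sites)
    n_freeze = len(feeder)
    feeder_sites = sites[feeder]
    freeze_frame = np.searchsorted(fronts, tau[feeder], side="left")

    # liquid base positions fill the space above the rough surface; sites
    # and liquid molecules are consumed in matching (freeze-time, z) order,
    # so the remaining liquid always tracks the front (ice and liquid
    # densities are within ~7%, so no gap opens)
    liq_vol = float(box[0] * box[1] * (box[2] - fronts[0]))
    n_liquid = int(round(params.liquid_density * liq_vol))
    near_surface = perm_sites[perm_sites[:, 2] > fronts[0] - w]
    liq_base = _rsa_positions(box, n_liquid, params.min_separation, rng,
                              z_range=(fronts[0] - w / 2 + 1.0, box[2] - 0.5),
                              fixed=near_surface)
    liq_base = liq_base[np.argsort(liq_base[:, 2], kind="stable")]
    if n_freeze > n_liquid:
        raise GenerationError("not enough liquid molecules to feed the front")

    # liquid rank r freezes onto feeder site r (inf = never freezes)
    liq_freeze_frame = np.full(n_liquid, np.inf)
    liq_freeze_frame[:n_freeze] = freeze_frame

    n_water = n_perm + n_liquid
    # molecule i: 0..n_perm-1 are permanent ice; the rest start liquid
    h_offsets = np.array([_random_water_orientation(rng) for _ in range(n_water)])

    # probe + chain + optional donor
    probe_xy = box[:2] / 2.0
    phi_sched = params.phi_at(times)
    species = ["OW"] * n_water
    if params.include_hydrogens:
        species += ["HW"] * (2 * n_water)
    probe_at = len(species)
    species.append("C_PROBE")
    species += ["C_CHAIN", "S_CHAIN", "S_CHAIN", "C_CHAIN"]
    donor_at = None
    if params.include_donor:
        donor_at = len(species)
        species += ["O_DONOR", "H_DONOR"]
    n_atoms = len(species)

    coords = np.empty((n_frames, n_atoms, 3))
    n_ice_truth = np.empty(n_frames, dtype=int)
    sigma_liq = params.thermal_noise
    sigma_ice = params.thermal_noise / 3.0
    for f in range(n_frames):
        base = np.empty((n_water, 3))
        base[:n_perm] = perm_sites
        frozen = liq_freeze_frame <= f
        base[n_perm:][frozen] = feeder_sites[frozen[:n_freeze]]
        # remaining liquid column is rescaled to track the front: freezing
        # expands (ice is less dense), pushing the liquid up
        unfrozen = liq_base[~frozen]
        if len(unfrozen):
            top = box[2] - 0.5
            target_lo = fronts[f] - w / 2 + 1.0
            bmin = unfrozen[:, 2].min()
            if top > bmin and top > target_lo:
                scale = (top - target_lo) / (top - bmin)
                unfrozen = unfrozen.copy()
                unfrozen[:, 2] = target_lo + (unfrozen[:, 2] - bmin) * scale
        base[n_perm:][~frozen] = unfrozen
        ice_mask = np.concatenate([np.ones(n_perm, bool), frozen])
        jit = np.where(ice_mask[:, None], sigma_ice, sigma_liq)
        opos = base + rng.normal(scale=1.0, size=(n_water, 3)) * jit
        coords[f, :n_water] = opos
        if params.include_hydrogens:
            hpos = (opos[:, None, :] + h_offsets).reshape(-1, 3)
            coords[f, n_water:n_water + 2 * n_water] = hpos
        n_ice_truth[f] = n_perm + int(frozen.sum())

        # probe: drift in from approach_distance to the hover standoff, then
        # bind (adsorb into a surface pocket) at t_bind.  The hover standoff
        # keeps the shell ice-free until the discrete binding event, which
        # is what an adsorption looks like at frame resolution.
        t = times[f]
        span = times[-1] if times[-1] > 0 else 1.0
        t_arrive = params.t_bind if params.t_bind is not None else span
        if params.t_bind is not None and t >= params.t_bind:
            offset = params.contact_distance
        else:
            frac = min(t / t_arrive, 1.0)
            offset = (params.approach_distance
                      + frac * (params.hover_distance - params.approach_distance))
        probe = np.array([probe_xy[0], probe_xy[1], fronts[f] + offset])
        coords[f, probe_at] = probe
        # C–S–S–C chain rides above the probe, dihedral = schedule
        c1 = probe + np.array([0.0, 0.0, 1.53])
        s1 = c1 + np.array([1.44, 0.0, 1.08])        # C–S 1.8 Å at ~53°
        s2 = place_fourth_atom(probe, c1, s1, 2.05, 104.0, 73.0)
        c2 = place_fourth_atom(c1, s1, s2, 1.80, 104.0, float(phi_sched[f]))
        coords[f, probe_at + 1:probe_at + 5] = [c1, s1, s2, c2]
        if donor_at is not None:
            od = probe + np.array([0.0, 2.4, 0.6])
            hd = od + np.array([0.0, 0.0, -OH_BOND])   # points toward the ice
            coords[f, donor_at] = od
            coords[f, donor_at + 1] = hd

    metadata = {
        "growth_rate": params.growth_rate,
        "t_bind": params.t_bind,
        "post_bind_rate_factor": params.post_bind_rate_factor,
        "front_truth": fronts,
        "n_ice_truth": n_ice_truth,
        "phi_schedule": phi_sched,
        "probe_index": probe_at,
        "chain_indices": list(range(probe_at + 1, probe_at + 5)),
        "donor_indices": None if donor_at is None else [donor_at, donor_at + 1],
        "exposed_face": "primary prismatic",
        "box_requested": requested_box,
        "n_waters": n_water,
        "seed": params.seed,
        "truncated": n_frames != params.n_frames,
    }
    return FrameSet(coords, np.array(species, dtype=object), box, times, metadata)


# ---------------------------------------------------------------------------
# conformer ensembles

from .nmr import ConformerEnsemble  # noqa: E402  (cycle-free: nmr has no synthetic import)


def generate_ensemble(n_models: int = 1500,
                      energy_distribution: tuple[float, float] = (0.0, 50.0),
                      rmsd_structure: str = "dominant",
                      seed: int = 0) -> ConformerEnsemble:
    """Synthetic cyclic-peptide conformer ensemble with known structure.

    Models carry strictly increasing energies drawn uniformly over
    ``energy_distribution`` and sorted.  ``rmsd_structure``:

    - ``"dominant"`` — model 0 is the planted representative: it has the
      lowest energy and the smallest deformation from the common base
      geometry (deformation grows with model index), so it wins both the
      energy rank and the mean-RMSD rank.
    - ``"two_cluster"`` — models split into two conformer families around
      two distinct base geometries (within-family spread ≪ between-family
      distance).
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(seed)
    from .scaffold import build_canonical_scaffold
    scaffold = build_canonical_scaffold()
    n_res = len(scaffold)
    theta = 2 * np.pi * np.arange(n_res) / n_res
    radius = n_res * 3.8 / (2 * np.pi)
    ca = np.stack([radius * np.cos(theta), radius * np.sin(theta),
                   0.3 * np.sin(3 * theta)], axis=1)
    labels = [(p, "CA") for p in range(1, n_res + 1)]
    cb_rows = [
        (p, ca[p - 1] * (1 + 1.53 / radius) + np.array([0.0, 0.0, 0.8]))
        for p in range(1, n_res + 1) if scaffold.residue(p) != "G"
    ]
    base = np.vstack([ca] + [row[1][None, :] for row in cb_rows])
    labels += [(p, "CB") for p, _ in cb_rows]

    lo, hi = energy_distribution
    energies = np.sort(rng.uniform(lo, hi, size=n_models))
    # enforce strict increase
    energies += np.arange(n_models) * 1e-9

    coords = np.empty((n_models, len(base), 3))
    if rmsd_structure == "dominant":
        # deformation grows steeply from model to model so the planted
        # model dominates the mean-RMSD rank within any low-energy shortlist
        scale = np.minimum(0.05 + 0.15 * np.arange(n_models), 2.0)
        for m in range(n_models):
            coords[m] = base + rng.normal(scale=scale[m], size=base.shape)
    elif rmsd_structure == "two_cluster":
        shift = np.array([6.0, 0.0, 0.0])
        flip = np.diag([1.0, -1.0, 1.0])
        base2 = base @ flip + shift
        half = n_models // 2
        for m in range(n_models):
            b = base if m < half else base2
            coords[m] = b + rng.normal(scale=0.3, size=base.shape)
    else:
        raise ValueError(f"unknown rmsd_structure {rmsd_structure!r}")
    meta = {"rmsd_structure": rmsd_structure, "seed": seed}
    if rmsd_structure == "dominant":
        meta["planted_representative"] = 0
    if rmsd_structure == "two_cluster":
        meta["cluster_of"] = (np.arange(n_models) >= n_models // 2).astype(int)
    return ConformerEnsemble(
        coordinates=coords,
        atom_labels=labels,
        energies=energies,
        model_ids=list(range(n_models)),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# grain maps


def generate_grain_map(width: int, height: int, n_grains: int,
                       seed: int = 0) -> np.ndarray:
    """Voronoi tessellation label map: every pixel labeled 1..n_grains by
    nearest seed point.  Emulates a segmented post-anneal ice wafer."""
    if n_grains < 1:
        raise ValueError("n_grains must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = rng.uniform([0, 0], [width, height], size=(n_grains, 2))
    ys, xs = np.mgrid[0:height, 0:width]
    pix = np.stack([xs.ravel() + 0.5, ys.ravel() + 0.5], axis=1)
    _, lab = cKDTree(seeds).query(pix)
    return (lab + 1).reshape(height, width).astype(np.int32)
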