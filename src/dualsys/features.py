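"""Sensory feature populations.

Two feature banks feed the two learning systems:

* **Landmark cells (LCs)** — egocentric input to the striatal learner.  Each
  cell is tuned to a particular landmark identity at a preferred egocentric
  distance ``d*`` and bearing ``theta*`` (0 = straight ahead, positive =
  counterclockwise), with a bivariate-Gaussian receptive field over
  (distance, wrapped angle).  A different set of LCs responds to each
  landmark identity; absent landmarks drive their cells at zero.

* **Boundary-vector cells (BVCs) and place cells** — allocentric input to the
  hippocampal successor-feature learner.  A BVC integrates a radial-Gaussian
  x angular-Gaussian tuning curve over all boundary segments, weighted by the
  subtended angle of each segment element, so nearer sections of wall at the
  preferred distance/direction drive the cell harder.  Place-cell rates are
  the thresholded sum of their BVC inputs, which yields localized fields in
  an enclosed box and stripe-like, less reliable fields when only a single
  isolated boundary (or landmark) is present.

Nonspatial tasks use plain one-hot state encodings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandmarkCellParams",
    "LandmarkCellBank",
    "BVCParams",
    "PlaceCellParams",
    "PlaceCellBank",
    "lc_activation",
    "lc_population",
    "bvc_activation",
    "place_cell_rates",
    "one_hot",
    "build_lc_bank",
    "build_place_cell_bank",
    "feature_table_lc",
    "feature_table_pc",
]


def wrap_angle(a):
    """Wrap angle(s) to [-pi, pi)."""
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi


# Within this range a landmark is underfoot: its egocentric bearing is
# undefined, so LC angular tuning is dropped (factor 1 for every cell) and
# only distance tuning applies.  Keeps LC populations rotation-invariant at
# the landmark location itself.
LC_NEAR_RADIUS = 0.5


# ---------------------------------------------------------------------- #
# landmark cells
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class LandmarkCellParams:
    d_pref: float
    theta_pref: float  # radians, [-pi, pi)
    sigma_d: float
    sigma_theta: float
    identity: str

    def __post_init__(self):
        if self.sigma_d <= 0 or self.sigma_theta <= 0:
            raise ValueError("tuning widths must be positive")


def lc_activation(d: float, theta: float, params: LandmarkCellParams) -> float:
    """Bivariate-Gaussian landmark-cell rate at egocentric (d, theta).

    Peak rate is normalized to 1 at the preferred (d*, theta*); the angular
    difference is wrapped to [-pi, pi).
    """
    if d < 0:
        raise ValueError("distance must be nonnegative")
    zd = (d - params.d_pref) / params.sigma_d
    if d < LC_NEAR_RADIUS:
        zt = 0.0
    else:
        zt = wrap_angle(theta - params.theta_pref) / params.sigma_theta
    return float(np.exp(-0.5 * (zd * zd + zt * zt)))


@dataclass
class LandmarkCellBank:
    """An ordered population of LCs covering a polar grid per identity."""

    cells: list[LandmarkCellParams]
    # vectorized tuning arrays (built once)
    _d: np.ndarray = field(init=False)
    _t: np.ndarray = field(init=False)
    _sd: np.ndarray = field(init=False)
    _st: np.ndarray = field(init=False)

    def __post_init__(self):
        self._d = np.array([c.d_pref for c in self.cells])
        self._t = np.array([c.theta_pref for c in self.cells])
        self._sd = np.array([c.sigma_d for c in self.cells])
        self._st = np.array([c.sigma_theta for c in self.cells])
        self._ident = np.array([c.identity for c in self.cells])

    @property
    def n_features(self) -> int:
        return len(self.cells)

    def rates(self, d_by_identity: dict[str, tuple[float, float]]) -> np.ndarray:
        """Population rates given {identity: (distance, ego angle)}."""
        out = np.zeros(self.n_features)
        for ident, (d, theta) in d_by_identity.items():
            m = self._ident == ident
            if not m.any():
                continue
            zd = (d - self._d[m]) / self._sd[m]
            if d < LC_NEAR_RADIUS:
                zt = np.zeros_like(zd)
            else:
                zt = wrap_angle(theta - self._t[m]) / self._st[m]
            out[m] = np.exp(-0.5 * (zd * zd + zt * zt))
        return out


def build_lc_bank(
    identities: list[str],
    radii=(2.0, 5.0, 9.0, 14.0),
    n_angles: int = 8,
    sigma_d: float = 2.5,
    sigma_theta: float = np.pi / 4,
) -> LandmarkCellBank:
    """Polar grid of preferred (distance, egocentric angle) per identity."""
    cells = []
    angles = wrap_angle(np.arange(n_angles) * 2 * np.pi / n_angles)
    for ident in identities:
        for d in radii:
            for th in angles:
                cells.append(
                    LandmarkCellParams(float(d), float(th), sigma_d, sigma_theta, ident)
                )
    return LandmarkCellBank(cells)


def lc_population(
    pose: tuple[float, float, float],
    landmarks: list[tuple[tuple[float, float], str]],
    bank: LandmarkCellBank,
) -> np.ndarray:
    """LC population vector for an agent at ``pose`` = (x, y, heading angle).

    The egocentric bearing of each landmark is its allocentric bearing minus
    the agent's heading; identities with no landmark present contribute zero.
    """
    x, y, heading = pose
    seen: dict[str, tuple[float, float]] = {}
    for (lx, ly), ident in landmarks:
        dx, dy = lx - x, ly - y
        d = float(np.hypot(dx, dy))
        theta = float(wrap_angle(np.arctan2(dy, dx) - heading))
        seen[ident] = (d, theta)
    return bank.rates(seen)


# ---------------------------------------------------------------------- #
# boundary-vector cells and place cells
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class BVCParams:
    phi_pref: float  # preferred allocentric direction (radians)
    d_pref: float  # preferred distance
    sigma0: float = 0.5  # radial width at distance 0
    beta: float = 8.0  # radial width growth scale: sigma_rad = sigma0*(1+d/beta)
    sigma_ang: float = 0.35  # angular width (radians)

    def __post_init__(self):
        if self.sigma0 <= 0 or self.sigma_ang <= 0 or self.beta <= 0:
            raise ValueError("tuning widths must be positive")

    @property
    def sigma_rad(self) -> float:
        return self.sigma0 * (1.0 + self.d_pref / self.beta)


def _segment_points(seg, ds: float):
    """Discretize a wall segment into element midpoints with arc length ds."""
    (x0, y0), (x1, y1) = seg
    length = float(np.hypot(x1 - x0, y1 - y0))
    n = max(1, int(np.ceil(length / ds)))
    t = (np.arange(n) + 0.5) / n
    pts = np.stack([x0 + t * (x1 - x0), y0 + t * (y1 - y0)], axis=1)
    return pts, length / n


def bvc_activation(
    position,
    walls,
    params: BVCParams,
    ds: float = 1.0,
) -> float:
    """BVC rate: boundary integral of radial x angular Gaussian tuning.

    Each wall element of arc length ``dl`` at distance ``r`` contributes in
    proportion to the angle it subtends (``dl / r``), so a nearer stretch of
    boundary at the preferred distance and direction produces a larger rate
    than a shorter or farther one.  Additive over disjoint segments.
    """
    if not walls:
        return 0.0
    x, y = position
    total = 0.0
    for seg in walls:
        pts, dl = _segment_points(seg, ds)
        dx, dy = pts[:, 0] - x, pts[:, 1] - y
        r = np.hypot(dx, dy)
        r = np.maximum(r, 1e-6)
        phi = np.arctan2(dy, dx)
        g_rad = np.exp(-0.5 * ((r - params.d_pref) / params.sigma_rad) ** 2)
        g_ang = np.exp(-0.5 * (wrap_angle(phi - params.phi_pref) / params.sigma_ang) ** 2)
        total += float(np.sum(g_rad * g_ang * dl / r))
    return total


@dataclass
class PlaceCellParams:
    """A place cell: thresholded-linear sum of its BVC inputs."""

    bvcs: list[BVCParams]
    threshold: float = 0.0
    label: str = ""

    def __post_init__(self):
        if not self.bvcs:
            raise ValueError("a place cell needs at least one BVC input")
        if self.threshold < 0:
            raise ValueError("threshold must be nonnegative")


def place_cell_rates(position, walls, bank: list[PlaceCellParams], ds: float = 1.0) -> np.ndarray:
    """Rates of a place-cell bank at an allocentric position (heading-free)."""
    out = np.empty(len(bank))
    for k, cell in enumerate(bank):
        drive = sum(bvc_activation(position, walls, b, ds=ds) for b in cell.bvcs)
        out[k] = max(0.0, drive - cell.threshold)
    return out


@dataclass
class PlaceCellBank:
    cells: list[PlaceCellParams]
    ds: float = 1.0
    # population rates are multiplied by this so the mean squared population
    # norm over the reference arena is ~1 (keeps TD step sizes comparable
    # across bank layouts)
    rate_scale: float = 1.0

    @property
    def n_features(self) -> int:
        return len(self.cells)

    def rates(self, position, walls) -> np.ndarray:
        return self.rate_scale * place_cell_rates(position, walls, self.cells, ds=self.ds)


def build_place_cell_bank(
    arena,
    spacing: int = 2,
    mode: str = "conjunctive",
    threshold_frac: float = 0.5,
    sigma0: float = 0.5,
    beta: float = 8.0,
    sigma_ang: float = 0.35,
    walls=None,
) -> PlaceCellBank:
    """Construct a place-cell bank tiling an arena.

    For each candidate field center (a coarse grid with ``spacing`` cells
    between centers) and each wall of the arena's full configuration, a BVC
    is tuned to the bearing and distance from the center to the nearest point
    of that wall.

    ``mode='conjunctive'`` makes one place cell per center combining the
    BVCs for all walls (localized fields in an enclosed box); ``'per_wall'``
    makes one cell per (center, wall) pair whose BVCs are all tuned to that
    single wall (nearest point plus the two wall endpoints, when distinct),
    the configuration used for open arenas with isolated boundaries: each
    cell lives and dies with its own boundary, while the endpoint tunings
    localize the field in both dimensions.

    Thresholds are set per cell to ``threshold_frac`` times that cell's peak
    drive over the arena under the full wall configuration.
    """
    walls = list(walls) if walls is not None else list(arena.walls)
    centers = arena.centers()
    nx, ny = arena.grid_shape
    coarse = [
        s
        for s, (i, j) in enumerate(arena._cells)
        if i % spacing == spacing // 2 and j % spacing == spacing // 2
    ]
    ds = arena.cell_size

    def nearest_on_wall(c, seg):
        p0, p1 = np.asarray(seg[0]), np.asarray(seg[1])
        v = p1 - p0
        t = np.clip(np.dot(c - p0, v) / max(np.dot(v, v), 1e-12), 0.0, 1.0)
        q = p0 + t * v
        d = float(np.hypot(*(q - c)))
        phi = float(np.arctan2(q[1] - c[1], q[0] - c[0]))
        return max(d, 0.5 * ds), phi

    def point_tuning(c, q):
        q = np.asarray(q, dtype=float)
        d = float(np.hypot(*(q - c)))
        phi = float(np.arctan2(q[1] - c[1], q[0] - c[0]))
        return max(d, 0.5 * ds), phi

    cells: list[PlaceCellParams] = []
    for s in coarse:
        c = centers[s]
        if mode == "conjunctive":
            bvcs = []
            for seg in walls:
                d, phi = nearest_on_wall(c, seg)
                bvcs.append(
                    BVCParams(phi, d, sigma0=sigma0, beta=beta, sigma_ang=sigma_ang)
                )
            cells.append(PlaceCellParams(bvcs, 0.0, label=f"pc{s}"))
        elif mode == "per_wall":
            for w, seg in enumerate(walls):
                d, phi = nearest_on_wall(c, seg)
                bvcs = [BVCParams(phi, d, sigma0=sigma0, beta=beta, sigma_ang=sigma_ang)]
                for q in seg:
                    dq, phiq = point_tuning(c, q)
                    if abs(dq - d) > ds:  # endpoint distinct from nearest point
                        bvcs.append(
                            BVCParams(
                                phiq, dq, sigma0=sigma0, beta=beta, sigma_ang=sigma_ang
                            )
                        )
                cells.append(PlaceCellParams(bvcs, 0.0, label=f"pc{s}w{w}"))
        else:
            raise ValueError(f"unknown bank mode {mode!r}")
    # per-cell threshold from peak drive under the full configuration
    bank = PlaceCellBank(cells, ds=ds)
    drives = feature_table_pc(arena, bank, walls=walls)  # thresholds still 0
    for k, cell in enumerate(cells):
        cell.threshold = float(threshold_frac * drives[:, k].max())
    F = feature_table_pc(arena, bank, walls=walls)
    msq = float(np.mean(np.sum(F * F, axis=1)))
    if msq > 0:
        bank.rate_scale = 1.0 / np.sqrt(msq)
    return bank


# ---------------------------------------------------------------------- #
# feature tables (precomputed lookups for the agent loop)
# ---------------------------------------------------------------------- #

def feature_table_lc(arena, bank: LandmarkCellBank) -> np.ndarray:
    """(n_states, n_headings, n_lc) LC rates at every cell center/heading."""
    S, H = arena.n_states, arena.n_actions
    out = np.zeros((S, H, bank.n_features))
    centers = arena.centers()
    head_angles = np.array([arena.heading_angle(h) for h in range(H)])
    for (lx, ly), ident in arena.landmarks:
        m = bank._ident == ident
        if not m.any():
            continue
        dx, dy = lx - centers[:, 0], ly - centers[:, 1]
        d = np.hypot(dx, dy)  # (S,)
        bearing = np.arctan2(dy, dx)
        # egocentric angle per state x heading
        theta = wrap_angle(bearing[:, None] - head_angles[None, :])  # (S, H)
        zd = (d[:, None, None] - bank._d[m]) / bank._sd[m]  # (S, 1, F)
        zt = wrap_angle(theta[:, :, None] - bank._t[m]) / bank._st[m]  # (S, H, F)
        zt = np.where(d[:, None, None] < LC_NEAR_RADIUS, 0.0, zt)
        out[:, :, m] = np.exp(-0.5 * (zd * zd + zt * zt))
    return out


def feature_table_pc(arena, bank: PlaceCellBank, walls=None) -> np.ndarray:
    """(n_states, n_pc) place-cell rates for a given wall configuration.

    Vectorized over states: all wall segments are discretized once and each
    BVC's boundary integral is evaluated for every cell center in one pass.
    """
    walls = list(walls) if walls is not None else list(arena.walls)
    centers = arena.centers()
    S = len(centers)
    out = np.zeros((S, bank.n_features))
    if not walls:
        return out
    pts_list, dl_list = [], []
    for seg in walls:
        pts, dl = _segment_points(seg, bank.ds)
        pts_list.append(pts)
        dl_list.append(np.full(len(pts), dl))
    pts = np.concatenate(pts_list)  # (P, 2)
    dl = np.concatenate(dl_list)  # (P,)
    dx = pts[None, :, 0] - centers[:, None, 0]  # (S, P)
    dy = pts[None, :, 1] - centers[:, None, 1]
    r = np.maximum(np.hypot(dx, dy), 1e-6)
    phi = np.arctan2(dy, dx)
    subtend = dl / r
    for k, cell in enumerate(bank.cells):
        drive = np.zeros(S)
        for b in cell.bvcs:
            g_rad = np.exp(-0.5 * ((r - b.d_pref) / b.sigma_rad) ** 2)
            g_ang = np.exp(-0.5 * (wrap_angle(phi - b.phi_pref) / b.sigma_ang) ** 2)
            drive += np.sum(g_rad * g_ang * subtend, axis=1)
        out[:, k] = np.maximum(0.0, drive - cell.threshold)
    return bank.rate_scale * out


def one_hot(index: int, n: int) -> np.ndarray:
    """Unit basis vector of length ``n``."""
    if not 0 <= index < n:
        raise ValueError(f"index {index} out of range for {n} states")
    v = np.zeros(n)
    v[index] = 1.0
    return v
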