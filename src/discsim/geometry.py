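"""Off-lattice cell geometry and mechanics.

Cells are soft discs characterised by a centre position and a radius.
Pairwise forces act only between pruned Delaunay neighbours: cells repel
when they overlap and attract weakly when there is a gap between them, so
that a cluster of cells packs itself into a roughly circular, centrally
compressed tissue.  Motion is overdamped: per-step displacement is
proportional to the net pairwise acceleration, with a hard cap for
numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MechanicsParams",
    "Disc",
    "pairwise_acceleration",
    "integrate_motion",
    "disc_radius",
    "init_disc",
]


@dataclass
class MechanicsParams:
    """Parameters of the two-body force law and overdamped integrator.

    The force law is piecewise: linear repulsion ``k_rep * (1 - d/d_eq)``
    inside contact, and an attraction ``-k_att * (x - 1) * exp(-(x-1)/lam)``
    (``x = d/d_eq``) outside contact that peaks near ``x = 1 + lam`` and
    decays to zero at long range.  ``d_eq`` is the sum of the two radii, so
    the force vanishes exactly when cells touch.
    """

    k_rep: float = 1.0
    k_att: float = 0.5
    lam: float = 0.5          # attraction range, in units of d_eq
    mobility: float = 0.4     # um displacement per unit acceleration per min
    cap_factor: float = 0.25  # displacement cap, in units of mean cell radius
    r_min: float = 0.3        # um, lower bound on cell radius
    r_max: float = 2.6        # um, upper bound on cell radius


class Disc:
    """Growing table of cell state, one row per cell (cell id == row index).

    Geometry fields are created here; free protein pools, adaptation
    integrators and polarity read-outs are carried on the same object and
    filled in by the kinetics / polarity machinery.  Cells are never
    removed, so ids are stable for the lifetime of a run.
    """

    def __init__(self, positions, radii, dt: float = 1.0, step: int = 0):
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        radii = np.atleast_1d(np.asarray(radii, dtype=float))
        n = radii.size
        if pos.shape != (n, 2):
            raise ValueError("positions must be (n, 2)")
        if np.any(radii <= 0) or not np.all(np.isfinite(pos)):
            raise ValueError("radii must be positive and positions finite")
        self.pos = pos.copy()
        self.radius = radii.copy()
        self.birth_step = np.zeros(n, dtype=np.int64)
        self.mother_id = np.full(n, -1, dtype=np.int64)
        self.region = np.zeros(n, dtype=np.int8)  # 0 = bulk, 1 = clone
        # deterministic sub-nm jitter, fixed at birth, used to break
        # cocircular ties in the triangulation
        self.jitter = np.zeros((n, 2), dtype=float)
        # free protein pools (molecule counts)
        self.ft_u = np.zeros(n, dtype=np.int64)
        self.ft_p = np.zeros(n, dtype=np.int64)
        self.ds_u = np.zeros(n, dtype=np.int64)
        self.ds_p = np.zeros(n, dtype=np.int64)
        # integral-feedback integrators (morphogen, Ft asymmetry, Ds asymmetry)
        self.y_m = np.zeros(n)
        self.y_ft = np.zeros(n)
        self.y_ds = np.zeros(n)
        # polarity read-outs (raw asymmetries and the Dachs vector)
        self.x_ft_raw = np.zeros(n)
        self.x_ds_raw = np.zeros(n)
        self.dachs = np.zeros((n, 2))
        self.dachs_mag = np.zeros(n)
        self.step = int(step)
        self.dt = float(dt)

    _PER_CELL = (
        "radius", "birth_step", "mother_id", "region",
        "ft_u", "ft_p", "ds_u", "ds_p",
        "y_m", "y_ft", "y_ds", "x_ft_raw", "x_ds_raw", "dachs_mag",
    )

    @property
    def n_cells(self) -> int:
        return self.radius.size

    def append_cell(self, pos, radius, birth_step, mother_id, region,
                    jitter=(0.0, 0.0)) -> int:
        """Add one cell and return its id.  Scalar per-cell state is zeroed."""
        new_id = self.n_cells
        self.pos = np.vstack([self.pos, np.asarray(pos, float)])
        self.jitter = np.vstack([self.jitter, np.asarray(jitter, float)])
        self.dachs = np.vstack([self.dachs, [0.0, 0.0]])
        for name in self._PER_CELL:
            arr = getattr(self, name)
            fill = np.zeros(1, dtype=arr.dtype)
            setattr(self, name, np.concatenate([arr, fill]))
        self.radius[new_id] = radius
        self.birth_step[new_id] = birth_step
        self.mother_id[new_id] = mother_id
        self.region[new_id] = region
        return new_id

    def centroid(self) -> np.ndarray:
        return self.pos.mean(axis=0)

    def radial_positions(self) -> np.ndarray:
        """Distance of each cell centre from the disc centroid, um."""
        d = self.pos - self.centroid()
        return np.hypot(d[:, 0], d[:, 1])


def pairwise_acceleration(d, d_eq, params: MechanicsParams | None = None):
    """Signed acceleration between two cells (positive = repulsive).

    Zero at contact (``d == d_eq``), positive (repulsive) inside, negative
    (attractive) outside, decaying to zero at long range.
    """
    params = params or MechanicsParams()
    d = np.asarray(d, dtype=float)
    d_eq = np.asarray(d_eq, dtype=float)
    if np.any(d_eq <= 0):
        raise ValueError("d_eq must be positive")
    if np.any(d < 0):
        raise ValueError("d must be non-negative")
    x = d / d_eq
    rep = params.k_rep * (1.0 - x)
    att = -params.k_att * (x - 1.0) * np.exp(-(x - 1.0) / params.lam)
    out = np.where(x < 1.0, rep, att)
    if out.ndim == 0:
        return float(out)
    return out


def integrate_motion(disc: Disc, edges: np.ndarray,
                     params: MechanicsParams | None = None,
                     dt: float | None = None) -> None:
    """One overdamped step: displace cells along net pairwise forces.

    ``edges`` is an (E, 2) array of pruned neighbour pairs.  Displacements
    are capped at ``cap_factor`` times the mean cell radius per step.
    """
    params = params or MechanicsParams()
    if dt is None:
        dt = disc.dt
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if edges.shape[0] == 0:
        return
    i, j = edges[:, 0], edges[:, 1]
    dvec = disc.pos[j] - disc.pos[i]
    dist = np.hypot(dvec[:, 0], dvec[:, 1])
    d_eq = disc.radius[i] + disc.radius[j]
    acc = pairwise_acceleration(np.maximum(dist, 0.0), d_eq, params)
    # coincident centres: push apart along a fixed axis
    safe = np.maximum(dist, 1e-12)
    unit = dvec / safe[:, None]
    unit[dist < 1e-12] = (1.0, 0.0)
    force_i = -np.atleast_1d(acc)[:, None] * unit
    disp = np.zeros_like(disc.pos)
    np.add.at(disp, i, force_i)
    np.add.at(disp, j, -force_i)
    disp *= params.mobility * dt
    cap = params.cap_factor * float(disc.radius.mean())
    norm = np.hypot(disp[:, 0], disp[:, 1])
    over = norm > cap
    if np.any(over):
        disp[over] *= (cap / norm[over])[:, None]
    disc.pos += disp


def disc_radius(disc: Disc) -> float:
    """Disc radius R: 99th percentile of (centroid distance + cell radius)."""
    if disc.n_cells == 0:
        raise ValueError("empty disc has no radius")
    return float(np.percentile(disc.radial_positions() + disc.radius, 99))


def _rejection_pack(n_cells: int, target_radius: float, radii: np.ndarray,
                    rng: np.random.Generator, max_tries: int = 40) -> np.ndarray:
    """Poisson-disc-like placement: sample positions in the target circle,
    rejecting candidates closer than ``sep_frac * (r_i + r_j)`` to an
    accepted cell.  If all tries fail the least-crowded candidate is kept,
    and the separation requirement is relaxed as the disc fills up."""
    pos = np.empty((n_cells, 2))
    sep_frac = 0.85
    for k in range(n_cells):
        best, best_score = None, -np.inf
        for _ in range(max_tries):
            r = (target_radius - radii[k]) * np.sqrt(rng.random())
            th = rng.random() * 2 * np.pi
            cand = np.array([r * np.cos(th), r * np.sin(th)])
            if k == 0:
                best = cand
                break
            d = np.hypot(*(pos[:k] - cand).T)
            score = float(np.min(d / (radii[:k] + radii[k])))
            if score >= sep_frac:
                best = cand
                break
            if score > best_score:
                best, best_score = cand, score
        pos[k] = best
    return pos


def init_disc(n_cells: int, target_radius: float = 40.0, seed=None,
              params: MechanicsParams | None = None,
              radius_range: tuple[float, float] = (1.1, 1.5),
              relax_steps: int = 200, dt: float = 1.0) -> Disc:
    """Build a mechanically relaxed disc of ``n_cells`` cells.

    Cells are placed by rejection sampling inside the target circle and the
    packing is then relaxed for ``relax_steps`` force-only steps, which
    compresses the centre relative to the periphery (adjacent cells
    attract).  With the default radius range a 1000-cell disc relaxes to an
    overall radius of about 40 um.
    """
    from .adjacency import pruned_edge_array  # local import, no cycle

    if n_cells < 3:
        raise ValueError("n_cells must be at least 3")
    if target_radius <= 0:
        raise ValueError("target_radius must be positive")
    params = params or MechanicsParams()
    rng = np.random.default_rng(seed)
    lo, hi = radius_range
    radii = rng.uniform(lo, hi, n_cells)
    pos = _rejection_pack(n_cells, target_radius, radii, rng)
    disc = Disc(pos, radii, dt=dt)
    disc.jitter = rng.uniform(-1e-9, 1e-9, size=(n_cells, 2))
    for _ in range(relax_steps):
        edges = pruned_edge_array(disc.pos + disc.jitter, disc.radius)
        integrate_motion(disc, edges, params, dt=dt)
    return disc
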