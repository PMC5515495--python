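"""Bond-asymmetry metrics, Dachs polarization, adaptation, growth, division.

The evenness of a cell's bonds over its mature neighbours is summarised by
the *adjusted minimum fraction*: the smallest per-neighbour bond count
divided by the total, multiplied by the number of neighbours (1 for a
perfectly even distribution, 0 when some neighbour shares no bonds).
Asymmetry x = 1 - adjusted minimum fraction drives both the Dachs vector
(which points toward the mature neighbour with the least bound Ft, with
magnitude equal to the Ft asymmetry) and a growth-rate boost.

Growth per step is multiplicative in radius,

    r_n / r_{n-1} = 1 + G0 (1 + C_Ft x_Ft)(1 + C_Ds x_Ds)(1 + C_M x_M) / (1 + U)

where the x's are adaptation-filtered signals (integral feedback: an
internal integrator tracks each raw signal, and only the excess over the
integrator drives growth, so constant inputs fade with time constant
tau_adapt) and U penalises free, unbound Ft and Ds.  Division probability
rises sharply (logistically) as the radius approaches a threshold; on
division, area is conserved, free pools split binomially, and every
mother-interface bond ledger follows the daughter that retains that
neighbour (split binomially when shared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from . import adjacency as adj_mod
from .kinetics import BondTable

__all__ = [
    "GrowthParams",
    "adjusted_min_fraction",
    "bond_asymmetries",
    "dachs_vector",
    "adapt",
    "growth_ratio",
    "division_probability",
    "divide_cell",
    "compute_polarity",
]


@dataclass
class GrowthParams:
    """Growth-law gains and division geometry.

    Calibrated so an average wild-type cell divides roughly every 8 h;
    the C gains keep every C*x product below unity.
    """

    G0: float = 7e-4          # per-step base growth of the radius ratio
    C_M: float = 0.9
    C_Ft: float = 0.9
    C_Ds: float = 0.9
    K_M: float = 1.0          # a.u., morphogen normalisation for x_M
    u_scale: float = 5e-4     # per free molecule
    tau_adapt: float = 300.0  # minutes
    r_div: float = 1.9        # um, division-threshold radius
    div_steepness: float = 0.05  # um


# ---------------------------------------------------------------------------
# asymmetry metrics
# ---------------------------------------------------------------------------

def adjusted_min_fraction(counts) -> float:
    """(min count / total) * n_neighbors.

    1 for a perfectly even distribution; 0 when any neighbour has zero
    bonds, when there are no bonds at all, or when the list is empty.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if c.size and np.any(c < 0):
        raise ValueError("bond counts must be non-negative")
    if c.size == 0:
        return 0.0
    total = c.sum()
    if total == 0:
        return 0.0
    return float(c.min() / total * c.size)


def bond_asymmetries(bound_ft_per_neighbor, bound_ds_per_neighbor,
                     count_bonds: bool = True) -> tuple[float, float]:
    """Raw asymmetries x = 1 - adjusted minimum fraction for a cell.

    The inputs are per-*mature*-neighbour bound-Ft and bound-Ds counts.
    Cells with no mature neighbours are recorded as unpolarised (x = 0);
    mature neighbours but no bonds give x = 1 (the mutant convention that
    produces ft-/ds- overgrowth).  When ``count_bonds`` is False (Ft
    lacking its intracellular domain) bonds are invisible to the cell and
    both asymmetries read 1.
    """
    ft = np.asarray(bound_ft_per_neighbor, dtype=np.int64).ravel()
    ds = np.asarray(bound_ds_per_neighbor, dtype=np.int64).ravel()
    if ft.size == 0 and ds.size == 0:
        return 0.0, 0.0
    if not count_bonds:
        ft = np.zeros_like(ft)
        ds = np.zeros_like(ds)
    return (1.0 - adjusted_min_fraction(ft) if ft.size else 0.0,
            1.0 - adjusted_min_fraction(ds) if ds.size else 0.0)


def dachs_vector(cell_pos, neighbor_positions, bound_ft_per_neighbor,
                 rng: np.random.Generator):
    """Dachs polarization of one cell.

    Direction: unit vector from the cell centre toward the mature
    neighbour with the least bound Ft (ties broken by a seeded random
    pick); magnitude: the bound-Ft asymmetry.  No mature neighbours ->
    ((0, 0), 0), i.e. unpolarised.
    """
    ft = np.asarray(bound_ft_per_neighbor, dtype=np.int64).ravel()
    if ft.size == 0:
        return np.zeros(2), 0.0
    npos = np.atleast_2d(np.asarray(neighbor_positions, dtype=float))
    lo = np.flatnonzero(ft == ft.min())
    pick = int(lo[0]) if lo.size == 1 else int(rng.choice(lo))
    d = npos[pick] - np.asarray(cell_pos, dtype=float)
    norm = np.hypot(*d)
    direction = d / norm if norm > 0 else np.zeros(2)
    return direction, 1.0 - adjusted_min_fraction(ft)


# ---------------------------------------------------------------------------
# adaptation and growth
# ---------------------------------------------------------------------------

def adapt(raw, y, tau_adapt: float, dt: float):
    """Integral-feedback filter: y <- y + (raw - y) dt / tau;
    adapted signal = max(0, raw - y).  Constant inputs fade to zero with
    time constant tau; a step input passes through almost unattenuated."""
    if tau_adapt <= 0:
        raise ValueError("tau_adapt must be positive")
    raw = np.asarray(raw, dtype=float)
    y = np.asarray(y, dtype=float)
    y_new = y + (raw - y) * (dt / tau_adapt)
    x = np.maximum(0.0, raw - y_new)
    if x.ndim == 0:
        return float(x), float(y_new)
    return x, y_new


def growth_ratio(x_m, x_ft, x_ds, U, params: GrowthParams):
    """Per-step radius ratio; always >= 1 (cells cannot shrink)."""
    num = ((1.0 + params.C_Ft * np.asarray(x_ft)) *
           (1.0 + params.C_Ds * np.asarray(x_ds)) *
           (1.0 + params.C_M * np.asarray(x_m)))
    out = 1.0 + params.G0 * num / (1.0 + np.asarray(U))
    return float(out) if np.ndim(out) == 0 else out


def division_probability(radius, params: GrowthParams):
    """Logistic per-step division probability, midpoint at r_div."""
    r = np.asarray(radius, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    out = expit((r - params.r_div) / params.div_steepness)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# division
# ---------------------------------------------------------------------------

def _binomial_split4(counts4: np.ndarray, rng) -> np.ndarray:
    return rng.binomial(np.asarray(counts4, dtype=np.int64), 0.5)


def divide_cell(disc, graph: adj_mod.NeighborGraph, bonds: BondTable,
                cell_id: int, rng: np.random.Generator,
                orientation_mode: str = "random") -> int:
    """Divide one cell; returns the new daughter's id.

    Daughters sit symmetrically about the mother's centre (offset half the
    mother radius each way) along the division axis, each with radius
    r / sqrt(2) (area conserved).  Free pools split binomially per state.
    Each mother-neighbour interface's bonds follow the daughter that
    retains that neighbour (binomial split when shared); the
    daughter-daughter interface starts bond-free with establishment step
    now.  Total protein and bonds are conserved exactly.
    """
    m = int(cell_id)
    if not (0 <= m < disc.n_cells):
        raise KeyError(f"unknown cell {cell_id}")
    r_m = float(disc.radius[m])
    centre = disc.pos[m].copy()
    if orientation_mode == "random":
        th = rng.random() * 2.0 * np.pi
        axis = np.array([np.cos(th), np.sin(th)])
    elif orientation_mode in ("radial", "tangential"):
        v = centre - disc.pos.mean(axis=0)
        n = np.hypot(*v)
        u = v / n if n > 0 else np.array([1.0, 0.0])
        axis = u if orientation_mode == "radial" else np.array([-u[1], u[0]])
    else:
        raise ValueError(f"unknown orientation mode {orientation_mode!r}")
    offset = 0.5 * r_m * axis

    d = disc.append_cell(centre + offset, r_m / np.sqrt(2.0),
                         birth_step=disc.step, mother_id=m,
                         region=disc.region[m],
                         jitter=rng.uniform(-1e-9, 1e-9, 2))
    disc.pos[m] = centre - offset
    disc.radius[m] = r_m / np.sqrt(2.0)
    disc.birth_step[m] = disc.step
    # daughters inherit the mother's adaptation state and read-outs
    for name in ("y_m", "y_ft", "y_ds", "x_ft_raw", "x_ds_raw"):
        getattr(disc, name)[d] = getattr(disc, name)[m]
    for name in ("ft_u", "ft_p", "ds_u", "ds_p"):
        pool = getattr(disc, name)
        share = rng.binomial(pool[m], 0.5)
        pool[d] = share
        pool[m] -= share

    assignment = graph.update_after_division(
        m, d, disc.pos + disc.jitter, disc.radius, disc.step)

    for n, side in assignment.items():
        for i, j in ((m, n), (n, m)):
            if side == "daughter":
                new = (d, j) if i == m else (i, d)
                bonds.rekey(i, j, *new)
            elif side == "both":
                c = bonds.get(i, j)
                if c.sum() == 0:
                    continue
                share = _binomial_split4(c, rng)
                if share.sum():
                    bonds.add(i, j, -share)
                    new = (d, j) if i == m else (i, d)
                    bonds.add(*new, share)
    return d


# ---------------------------------------------------------------------------
# vectorised per-step polarity (engine path)
# ---------------------------------------------------------------------------

def compute_polarity(disc, graph: adj_mod.NeighborGraph, bonds: BondTable,
                     grace_period: int, rng: np.random.Generator,
                     count_bonds: bool = True) -> None:
    """Fill disc.x_ft_raw / x_ds_raw / dachs / dachs_mag for every cell.

    Works on the directed-interface representation of the mature pruned
    edges and is equivalent to calling :func:`bond_asymmetries` and
    :func:`dachs_vector` cell by cell.
    """
    n = disc.n_cells
    disc.x_ft_raw[:] = 0.0
    disc.x_ds_raw[:] = 0.0
    disc.dachs[:] = 0.0
    disc.dachs_mag[:] = 0.0
    edges = graph.edges
    if edges.shape[0] == 0:
        return
    est = graph.est_of(edges)
    mature = (disc.step - est) >= grace_period
    edges = edges[mature]
    if edges.shape[0] == 0:
        return
    E = edges.shape[0]
    own = np.concatenate([edges[:, 0], edges[:, 1]])   # cell whose view this is
    nbr = np.concatenate([edges[:, 1], edges[:, 0]])
    # bound Ft of `own` toward `nbr` lives in ledger row (own, nbr);
    # bound Ds of `own` toward `nbr` in row (nbr, own).
    D = 2 * E
    partner = (np.arange(D) + E) % D
    if len(bonds):
        idx_ft = bonds.lookup_rows(np.column_stack([own, nbr]))
        totals = bonds.counts.sum(axis=1)
        bft = np.where(idx_ft >= 0, totals[idx_ft], 0)
    else:
        bft = np.zeros(D, dtype=np.int64)
    bds = bft[partner]
    if not count_bonds:
        bft = np.zeros_like(bft)
        bds = np.zeros_like(bds)

    n_mat = np.bincount(own, minlength=n)
    has = n_mat > 0

    def _asym(vals):
        tot = np.zeros(n, dtype=np.int64)
        np.add.at(tot, own, vals)
        mn = np.full(n, np.iinfo(np.int64).max)
        np.minimum.at(mn, own, vals)
        x = np.zeros(n)
        nz = has & (tot > 0)
        x[nz] = 1.0 - mn[nz] / tot[nz] * n_mat[nz]
        x[has & (tot == 0)] = 1.0
        return np.clip(x, 0.0, 1.0)

    disc.x_ft_raw[:] = _asym(bft)
    disc.x_ds_raw[:] = _asym(bds)

    # Dachs: toward the mature neighbour with least bound Ft (random ties)
    tie = rng.random(D)
    order = np.lexsort((tie, bft, own))
    so = own[order]
    first = np.r_[True, np.diff(so) > 0]
    sel = order[first]
    cells = own[sel]
    targets = nbr[sel]
    vec = disc.pos[targets] - disc.pos[cells]
    norm = np.hypot(vec[:, 0], vec[:, 1])
    norm[norm == 0] = 1.0
    disc.dachs[cells] = vec / norm[:, None]
    disc.dachs_mag[cells] = disc.x_ft_raw[cells]
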