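"""Ft/Ds pools, phosphorylation, and stochastic heterodimer bond kinetics.

Each cell carries integer pools of free Fat and Dachsous, split into
unphosphorylated and phosphorylated states.  Newly expressed protein is
phosphorylated with probability fj / (fj + phos_K); membrane protein is
never phosphorylated after the fact, and only *free* protein can
dephosphorylate or degrade.  Every step a cell partitions its free pools
evenly across its current interfaces, and each interface performs
K = min(#Ft, #Ds) independent pairing attempts: an attempt draws one Ft
and one Ds uniformly from the remaining allocations and succeeds with a
probability set by the pair's phosphorylation states (0.05 for Ft-Ds,
0.7 for FtP-Ds, 0.05 for Ft-DsP, 0.2 for FtP-DsP — phosphorylation makes
Ft stickier and Ds less sticky).  Failed participants return to the free
pool.  Bonds dissolve and free protein degrades by binomial thinning at
rate * dt per step.

Bond bookkeeping is a single shared ledger: row (i, j) counts the
heterodimers whose Ft belongs to cell i and whose Ds belongs to cell j,
by phosphorylation type (columns uu, pu, up, pp; Ft state first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KineticParams",
    "ProteinPools",
    "BondTable",
    "express_proteins",
    "partition_free",
    "partition_free_all",
    "form_bonds",
    "form_bonds_expected",
    "pair_and_bind",
    "dissolve_bonds",
    "degrade_free",
    "dephosphorylate",
    "step_probability",
]

#: bond-type column order: (Ft_u-Ds_u, Ft_p-Ds_u, Ft_u-Ds_p, Ft_p-Ds_p)
BOND_COLUMNS = ("n_uu", "n_pu", "n_up", "n_pp")


@dataclass
class KineticParams:
    """Rates (per minute) and binding weights of the Ft-Ds cycle."""

    k_dissoc: float = 0.08
    k_deg_ft: float = 0.08
    k_deg_ds: float = 0.08
    k_dephos: float = 0.02
    ft_rate: float = 40.0          # molecules / min, uniform across the disc
    phos_K: float = 0.5            # a.u., Fj half-saturation of phosphorylation
    # binding weights, indexed like BOND_COLUMNS
    w: tuple[float, float, float, float] = (0.05, 0.7, 0.05, 0.2)

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("binding weights must lie in [0, 1]")
        if not (w[1] > w[0] and w[2] <= w[0]):
            raise ValueError("weights must make FtP stickier and DsP less "
                             "sticky than the unphosphorylated forms")
        for k in (self.k_dissoc, self.k_deg_ft, self.k_deg_ds, self.k_dephos):
            if k < 0:
                raise ValueError("rates must be non-negative")


def step_probability(rate: float, dt: float) -> float:
    """Per-step event probability for a first-order rate: rate * dt,
    clipped to [0, 1] (per-step probabilities in the source model are the
    literal rate at dt = 1; clipping keeps large-rate / large-dt variants
    well defined)."""
    p = rate * dt
    if p < 0:
        raise ValueError("negative rate")
    return min(p, 1.0)


@dataclass
class ProteinPools:
    """Free (unbound) protein counts; arrays of any common shape."""

    ft_u: np.ndarray
    ft_p: np.ndarray
    ds_u: np.ndarray
    ds_p: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "ProteinPools":
        return cls(*(np.zeros(n, dtype=np.int64) for _ in range(4)))

    def total_ft(self):
        return self.ft_u + self.ft_p

    def total_ds(self):
        return self.ds_u + self.ds_p


# ---------------------------------------------------------------------------
# expression / decay / phosphorylation
# ---------------------------------------------------------------------------

def express_proteins(pools: ProteinPools, fj_level, ds_rate, params: KineticParams,
                     dt: float, rng: np.random.Generator,
                     ft_rate=None) -> ProteinPools:
    """Add Poisson(rate * dt) new Ft and Ds; each *new* molecule is
    phosphorylated independently with probability fj / (fj + phos_K).
    Existing membrane protein is never phosphorylated."""
    if ft_rate is None:
        ft_rate = params.ft_rate
    shape = np.shape(pools.ft_u)
    new_ft = rng.poisson(np.broadcast_to(np.asarray(ft_rate, float) * dt, shape))
    new_ds = rng.poisson(np.broadcast_to(np.asarray(ds_rate, float) * dt, shape))
    fj = np.asarray(fj_level, dtype=float)
    with np.errstate(invalid="ignore"):
        p_phos = np.where(fj + params.phos_K > 0, fj / (fj + params.phos_K), 0.0)
    ft_p_new = rng.binomial(new_ft, np.broadcast_to(p_phos, shape))
    ds_p_new = rng.binomial(new_ds, np.broadcast_to(p_phos, shape))
    pools.ft_u += new_ft - ft_p_new
    pools.ft_p += ft_p_new
    pools.ds_u += new_ds - ds_p_new
    pools.ds_p += ds_p_new
    return pools


def degrade_free(pools: ProteinPools, k_deg_ft: float, k_deg_ds: float,
                 dt: float, rng: np.random.Generator) -> ProteinPools:
    """Binomial thinning of the free pools; bound protein is untouched."""
    p_ft = step_probability(k_deg_ft, dt)
    p_ds = step_probability(k_deg_ds, dt)
    pools.ft_u -= rng.binomial(pools.ft_u, p_ft)
    pools.ft_p -= rng.binomial(pools.ft_p, p_ft)
    pools.ds_u -= rng.binomial(pools.ds_u, p_ds)
    pools.ds_p -= rng.binomial(pools.ds_p, p_ds)
    return pools


def dephosphorylate(pools: ProteinPools, k_dephos: float, dt: float,
                    rng: np.random.Generator) -> ProteinPools:
    """Move free phosphorylated protein back to the unphosphorylated pool;
    totals are conserved and bound protein keeps its state."""
    p = step_probability(k_dephos, dt)
    d_ft = rng.binomial(pools.ft_p, p)
    d_ds = rng.binomial(pools.ds_p, p)
    pools.ft_p -= d_ft
    pools.ft_u += d_ft
    pools.ds_p -= d_ds
    pools.ds_u += d_ds
    return pools


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def partition_free(count: int, n_neighbors: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Split ``count`` molecules evenly over ``n_neighbors`` interfaces:
    allocations differ by at most one, with the remainder placed on
    uniformly random interfaces.  Zero neighbours -> empty allocation."""
    if n_neighbors < 0:
        raise ValueError("n_neighbors must be >= 0")
    if n_neighbors == 0:
        return np.zeros(0, dtype=np.int64)
    base, rem = divmod(int(count), n_neighbors)
    alloc = np.full(n_neighbors, base, dtype=np.int64)
    if rem:
        alloc[rng.choice(n_neighbors, size=rem, replace=False)] += 1
    return alloc


def partition_free_all(pool: np.ndarray, owner: np.ndarray, n_cells: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Vectorised even split: for every cell, distribute ``pool[cell]``
    over its directed interfaces (the rows of ``owner`` equal to it),
    allocations differing by at most one with remainders on random
    interfaces.  Returns a per-row allocation aligned with ``owner``."""
    D = owner.size
    if D == 0:
        return np.zeros(0, dtype=np.int64)
    deg = np.bincount(owner, minlength=n_cells)
    deg_row = deg[owner]
    base = pool[owner] // deg_row
    rem_row = pool[owner] % deg_row
    u = rng.random(D)
    order = np.lexsort((u, owner))
    so = owner[order]
    starts = np.r_[0, np.flatnonzero(np.diff(so)) + 1]
    sizes = np.diff(np.r_[starts, D])
    rank_sorted = np.arange(D) - np.repeat(starts, sizes)
    rank = np.empty(D, dtype=np.int64)
    rank[order] = rank_sorted
    return base + (rank < rem_row)


# ---------------------------------------------------------------------------
# bond formation
# ---------------------------------------------------------------------------

def _hyp(rng, ngood, nbad, nsample):
    """Vectorised hypergeometric guarded against zero-size draws."""
    ngood = np.asarray(ngood, dtype=np.int64)
    nbad = np.asarray(nbad, dtype=np.int64)
    nsample = np.asarray(nsample, dtype=np.int64)
    out = np.zeros(np.broadcast_shapes(ngood.shape, nbad.shape, nsample.shape),
                   dtype=np.int64)
    ngood, nbad, nsample = np.broadcast_arrays(ngood, nbad, nsample)
    ok = nsample > 0
    if np.any(ok):
        out[ok] = rng.hypergeometric(ngood[ok], nbad[ok], nsample[ok])
    return out


def pair_and_bind(ft_u, ft_p, ds_u, ds_p, w, rng: np.random.Generator):
    """Core pairing scheme for one or many interfaces (vectorised).

    Performs K = min(total Ft, total Ds) pairing attempts per interface.
    Drawing attempt participants uniformly without replacement is
    equivalent to pairing random permutations of the two allocations, so
    the composition of the K attempted pairs follows nested
    hypergeometric draws; each pair then binds with its type weight.
    Returns an (..., 4) array of new bonds in BOND_COLUMNS order.
    """
    ft_u = np.asarray(ft_u, dtype=np.int64)
    ft_p = np.asarray(ft_p, dtype=np.int64)
    ds_u = np.asarray(ds_u, dtype=np.int64)
    ds_p = np.asarray(ds_p, dtype=np.int64)
    K = np.minimum(ft_u + ft_p, ds_u + ds_p)
    k_ftp = _hyp(rng, ft_p, ft_u, K)          # phosphorylated Ft among the K
    k_dsp = _hyp(rng, ds_p, ds_u, K)          # phosphorylated Ds among the K
    x = _hyp(rng, k_ftp, K - k_ftp, k_dsp)    # FtP paired with DsP
    pairs = np.stack([K - k_ftp - k_dsp + x,  # uu
                      k_ftp - x,              # pu
                      k_dsp - x,              # up
                      x], axis=-1)            # pp
    w = np.asarray(w, dtype=float)
    return rng.binomial(pairs, w)


def form_bonds(alloc_ft, alloc_ds, w, rng: np.random.Generator):
    """Single-interface bond formation per the pairing scheme.

    ``alloc_ft`` and ``alloc_ds`` are (unphos, phos) allocations of the
    two cells facing this interface.  Returns ``(bonds, leftover_ft,
    leftover_ds)``; failed participants are part of the leftovers and
    return to the free pools.
    """
    fu, fp = (int(v) for v in alloc_ft)
    du, dp = (int(v) for v in alloc_ds)
    if min(fu, fp, du, dp) < 0:
        raise ValueError("allocations must be non-negative")
    bonds = pair_and_bind(fu, fp, du, dp, w, rng)
    leftover_ft = np.array([fu - bonds[0] - bonds[2], fp - bonds[1] - bonds[3]])
    leftover_ds = np.array([du - bonds[0] - bonds[1], dp - bonds[2] - bonds[3]])
    return bonds, leftover_ft, leftover_ds


def form_bonds_expected(alloc_ft, alloc_ds, w) -> np.ndarray:
    """Deterministic-expectation variant: rounded expected bond counts of
    the pairing scheme (useful for closed-form checks)."""
    fu, fp = (float(v) for v in alloc_ft)
    du, dp = (float(v) for v in alloc_ds)
    ftot, dtot = fu + fp, du + dp
    K = min(ftot, dtot)
    if K == 0:
        return np.zeros(4, dtype=np.int64)
    w = np.asarray(w, dtype=float)
    frac = np.array([(fu / ftot) * (du / dtot), (fp / ftot) * (du / dtot),
                     (fu / ftot) * (dp / dtot), (fp / ftot) * (dp / dtot)])
    return np.rint(K * frac * w).astype(np.int64)


# ---------------------------------------------------------------------------
# bond ledger
# ---------------------------------------------------------------------------

def dissolve_bonds(counts: np.ndarray, k_dissoc: float, dt: float,
                   rng: np.random.Generator):
    """Binomial thinning of bond counts; returns (remaining, released).

    ``released`` has the same type layout; the Ft side goes back to the
    row's first cell and the Ds side to its second, states preserved.
    """
    p = step_probability(k_dissoc, dt)
    counts = np.asarray(counts, dtype=np.int64)
    released = rng.binomial(counts, p)
    return counts - released, released


class BondTable:
    """Shared ledger of Ft-Ds heterodimers.

    Row key (i, j): Ft contributed by cell i, Ds by cell j.  A single
    ledger guarantees that the bound-Ft count cell i sees toward j equals
    the bound-Ds count cell j sees toward i.
    """

    def __init__(self):
        self.pairs = np.empty((0, 2), dtype=np.int64)
        self.counts = np.empty((0, 4), dtype=np.int64)
        self._index: dict[tuple[int, int], int] = {}

    def __len__(self) -> int:
        return self.pairs.shape[0]

    def total(self) -> int:
        return int(self.counts.sum())

    def index_of(self, i: int, j: int) -> int:
        return self._index.get((i, j), -1)

    def get(self, i: int, j: int) -> np.ndarray:
        k = self._index.get((i, j), -1)
        if k < 0:
            return np.zeros(4, dtype=np.int64)
        return self.counts[k].copy()

    def _new_row(self, i: int, j: int) -> int:
        k = len(self)
        self.pairs = np.vstack([self.pairs, [[i, j]]])
        self.counts = np.vstack([self.counts, np.zeros((1, 4), np.int64)])
        self._index[(i, j)] = k
        return k

    def add(self, i: int, j: int, counts4) -> None:
        k = self._index.get((i, j), -1)
        if k < 0:
            k = self._new_row(i, j)
        self.counts[k] += np.asarray(counts4, dtype=np.int64)

    def add_many(self, pairs: np.ndarray, counts: np.ndarray) -> None:
        """Batched add; rows with all-zero counts are skipped."""
        nz = counts.sum(axis=1) > 0
        new_pairs, new_counts = [], []
        for (i, j), c in zip(pairs[nz], counts[nz]):
            k = self._index.get((int(i), int(j)), -1)
            if k < 0:
                new_pairs.append((int(i), int(j)))
                new_counts.append(c)
            else:
                self.counts[k] += c
        if new_pairs:
            start = len(self)
            self.pairs = np.vstack([self.pairs, np.asarray(new_pairs, np.int64)])
            self.counts = np.vstack([self.counts,
                                     np.asarray(new_counts, np.int64)])
            for off, key in enumerate(new_pairs):
                self._index[key] = start + off

    def lookup_rows(self, pairs: np.ndarray) -> np.ndarray:
        """Row index for each (i, j) pair; -1 where absent."""
        idx = self._index
        return np.fromiter((idx.get((int(a), int(b)), -1) for a, b in pairs),
                           dtype=np.int64, count=len(pairs))

    def rekey(self, i: int, j: int, new_i: int, new_j: int) -> None:
        k = self._index.pop((i, j), -1)
        if k < 0:
            return
        self.pairs[k] = (new_i, new_j)
        existing = self._index.get((new_i, new_j), -1)
        if existing >= 0:
            self.counts[existing] += self.counts[k]
            self.counts[k] = 0
            self.pairs[k] = (-1, -1)
        else:
            self._index[(new_i, new_j)] = k

    def pairs_involving(self, cell: int) -> list[tuple[int, int]]:
        return [p for p in self._index if cell in p]

    def compact(self) -> None:
        """Drop empty rows and rebuild the index."""
        keep = self.counts.sum(axis=1) > 0
        self.pairs = self.pairs[keep]
        self.counts = self.counts[keep]
        self._index = {(int(a), int(b)): k
                       for k, (a, b) in enumerate(self.pairs)}

    # per-cell aggregates ------------------------------------------------

    def bound_ft_per_cell(self, n_cells: int) -> np.ndarray:
        out = np.zeros(n_cells, dtype=np.int64)
        if len(self):
            np.add.at(out, self.pairs[:, 0], self.counts.sum(axis=1))
        return out

    def bound_ds_per_cell(self, n_cells: int) -> np.ndarray:
        out = np.zeros(n_cells, dtype=np.int64)
        if len(self):
            np.add.at(out, self.pairs[:, 1], self.counts.sum(axis=1))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.pairs, columns=["cell_i", "cell_j"])
        for k, name in enumerate(BOND_COLUMNS):
            df[name] = self.counts[:, k] if len(self) else np.empty(0, np.int64)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BondTable":
        t = cls()
        if len(df):
            t.pairs = df[["cell_i", "cell_j"]].to_numpy(dtype=np.int64)
            t.counts = df[list(BOND_COLUMNS)].to_numpy(dtype=np.int64)
            t._index = {(int(a), int(b)): k
                        for k, (a, b) in enumerate(t.pairs)}
        return t
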