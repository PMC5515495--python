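"""Derived summaries, snapshot tables, and run persistence.

Snapshots are plain pandas tables (one row per cell, per edge, or per
bond ledger row); runs persist as a directory of CSV tables plus a JSON
metadata file that includes the generator state, so a resumed run
continues bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import fields as fields_mod
from . import geometry
from .adjacency import NeighborGraph
from .kinetics import BOND_COLUMNS, BondTable

SCHEMA_VERSION = 1

__all__ = [
    "RunRecord", "SchemaError", "snapshot_tables", "summarize_snapshot",
    "radial_profile", "polarization_map", "distal_alignment",
    "disc_size_comparison", "write_snapshot", "read_snapshot",
    "write_run_dir",
]


class SchemaError(RuntimeError):
    """Snapshot directory is missing files or has the wrong version."""


@dataclass
class RunRecord:
    """Snapshots at the recording cadence plus derived per-run series."""

    run_config: object = None
    scenario: object = None
    summaries: list = field(default_factory=list)
    snapshots: dict = field(default_factory=dict)   # step -> cells DataFrame
    final_state: object = None

    @property
    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.summaries)

    @property
    def final_cell_count(self) -> int:
        if self.final_state is not None:
            return self.final_state.disc.n_cells
        return int(self.summary["n_cells"].iloc[-1])


# ---------------------------------------------------------------------------
# snapshot construction
# ---------------------------------------------------------------------------

def cells_dataframe(disc) -> pd.DataFrame:
    centroid = disc.pos.mean(axis=0)
    r = np.hypot(*(disc.pos - centroid).T)
    return pd.DataFrame({
        "id": np.arange(disc.n_cells),
        "mother_id": disc.mother_id,
        "x_um": disc.pos[:, 0], "y_um": disc.pos[:, 1],
        "radius_um": disc.radius, "birth_step": disc.birth_step,
        "region": disc.region, "radial_um": r,
        "ft_u": disc.ft_u, "ft_p": disc.ft_p,
        "ds_u": disc.ds_u, "ds_p": disc.ds_p,
        "x_ft": disc.x_ft_raw, "x_ds": disc.x_ds_raw,
        "dachs_dx": disc.dachs[:, 0], "dachs_dy": disc.dachs[:, 1],
        "dachs_magnitude": disc.dachs_mag,
        "y_m": disc.y_m, "y_ft": disc.y_ft, "y_ds": disc.y_ds,
    })


def snapshot_tables(state) -> pd.DataFrame:
    """The per-cell table recorded at each cadence step."""
    return cells_dataframe(state.disc)


def summarize_snapshot(state) -> dict:
    disc = state.disc
    sc = state.scenario
    R = geometry.disc_radius(disc)
    t = disc.step * disc.dt
    fr = fields_mod.front_radius(t, R, sc.morphogen, sc.ds_rule)
    cells = cells_dataframe(disc)
    inside = cells[cells["dachs_magnitude"] > 0]
    return {
        "step": disc.step,
        "n_cells": disc.n_cells,
        "disc_radius_um": R,
        "front_radius_um": np.nan if fr is None else fr,
        "mean_x_ft": float(disc.x_ft_raw.mean()),
        "mean_dachs_mag": float(disc.dachs_mag.mean()),
        "mean_distal_alignment": (distal_alignment(cells)
                                  if len(inside) else np.nan),
        "n_bonds": state.bonds.total(),
    }


# ---------------------------------------------------------------------------
# derived summaries
# ---------------------------------------------------------------------------

def radial_profile(cells: pd.DataFrame, quantity: str, n_bins: int = 20,
                   R: float | None = None) -> pd.DataFrame:
    """Binned mean +/- sd of a per-cell quantity vs radial position.

    Equal-width bins on [0, R]; empty bins are reported with NaN means
    (missing, not zero).
    """
    valid = [c for c in cells.columns if c not in ("id", "mother_id")]
    if quantity not in cells.columns:
        raise KeyError(f"unknown quantity {quantity!r}; valid: {sorted(valid)}")
    r = cells["radial_um"].to_numpy()
    if R is None:
        R = float(r.max()) or 1.0
    edges = np.linspace(0.0, R, n_bins + 1)
    idx = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    q = cells[quantity].to_numpy(dtype=float)
    rows = []
    for b in range(n_bins):
        sel = q[idx == b]
        rows.append({
            "bin_center": 0.5 * (edges[b] + edges[b + 1]),
            "mean": sel.mean() if sel.size else np.nan,
            "sd": sel.std(ddof=0) if sel.size else np.nan,
            "n": int(sel.size),
        })
    return pd.DataFrame(rows)


def aggregate_radial_profiles(profiles: list[pd.DataFrame]) -> pd.DataFrame:
    """Average per-bin means over replicate runs (equal weighting)."""
    out = profiles[0][["bin_center", "n"]].copy()
    means = np.stack([p["mean"].to_numpy() for p in profiles])
    out["mean"] = np.nanmean(means, axis=0)
    out["sd"] = np.nanstd(means, axis=0)
    return out


def polarization_map(cells: pd.DataFrame, smoothing_radius: float = 5.0,
                     grid_spacing: float = 4.0) -> pd.DataFrame:
    """Spatially smoothed Dachs field on a square grid.

    Each grid point within reach of at least one cell reports the vector
    mean of the Dachs vectors (anti-aligned cells cancel) and the scalar
    mean of their magnitudes; unreached points are omitted.
    """
    if smoothing_radius <= 0:
        raise ValueError("smoothing_radius must be positive")
    pos = cells[["x_um", "y_um"]].to_numpy()
    vec = (cells[["dachs_dx", "dachs_dy"]].to_numpy()
           * cells["dachs_magnitude"].to_numpy()[:, None])
    mag = cells["dachs_magnitude"].to_numpy()
    tree = cKDTree(pos)
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    gx = np.arange(lo[0], hi[0] + grid_spacing, grid_spacing)
    gy = np.arange(lo[1], hi[1] + grid_spacing, grid_spacing)
    pts = np.array([(x, y) for x in gx for y in gy])
    rows = []
    for (x, y), hits in zip(pts, tree.query_ball_point(pts, smoothing_radius)):
        if not hits:
            continue
        rows.append({
            "x_um": x, "y_um": y,
            "vx": vec[hits, 0].mean(), "vy": vec[hits, 1].mean(),
            "mean_magnitude": mag[hits].mean(), "n_cells": len(hits),
        })
    return pd.DataFrame(rows)


def distal_alignment(cells: pd.DataFrame, region=None) -> float:
    """Mean cosine between Dachs direction and the inward radial direction.

    +1: every polarised cell points at the disc centre (distal); 0:
    isotropic; -1: all outward (proximal).  Cells with zero Dachs
    magnitude are excluded; an empty region yields NaN.
    """
    df = cells if region is None else cells[region]
    df = df[df["dachs_magnitude"] > 0]
    if len(df) == 0:
        return float("nan")
    centroid = (cells["x_um"].mean(), cells["y_um"].mean())
    inward = np.column_stack([centroid[0] - df["x_um"],
                              centroid[1] - df["y_um"]])
    norm = np.hypot(inward[:, 0], inward[:, 1])
    norm[norm == 0] = 1.0
    inward /= norm[:, None]
    d = df[["dachs_dx", "dachs_dy"]].to_numpy()
    return float((inward * d).sum(axis=1).mean())


def disc_size_comparison(records_by_genotype: dict) -> pd.DataFrame:
    """Mean final cell counts and ratios to wild type, per genotype.

    ``records_by_genotype`` maps genotype name -> list of RunRecords; all
    runs must share a run length.  The wild-type entry is the reference.
    """
    lengths = {rec.summary["step"].iloc[-1]
               for recs in records_by_genotype.values() for rec in recs}
    if len(lengths) > 1:
        raise ValueError(f"mismatched run lengths: {sorted(lengths)}")
    if "wildtype" not in records_by_genotype:
        raise ValueError("need a 'wildtype' entry as the reference")
    counts = {g: np.array([rec.final_cell_count for rec in recs], float)
              for g, recs in records_by_genotype.items()}
    wt = counts["wildtype"].mean()
    rows = [{"genotype": g,
             "mean_cells": c.mean(),
             "ratio_to_wildtype": c.mean() / wt,
             "replicate_sd": c.std(ddof=0)}
            for g, c in counts.items()]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def _scenario_config_dict(config) -> dict:
    d = dataclasses.asdict(config)
    return d


def write_snapshot(state, path) -> None:
    """Write a self-contained, resumable state directory (CSV + JSON)."""
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    disc = state.disc
    cells = cells_dataframe(disc)
    cells["jitter_x"] = disc.jitter[:, 0]
    cells["jitter_y"] = disc.jitter[:, 1]
    # %.17g round-trips float64 exactly; resume must be bit-identical
    cells.to_csv(path / "cells.csv", index=False, float_format="%.17g")
    edges = state.graph.edges
    pd.DataFrame({
        "cell_a": edges[:, 0], "cell_b": edges[:, 1],
        "established_step": state.graph.est_of(edges) if len(edges) else [],
    }).to_csv(path / "edges.csv", index=False)
    state.bonds.compact()
    state.bonds.to_dataframe().to_csv(path / "bonds.csv", index=False)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "step": disc.step,
        "dt": disc.dt,
        "clone_active": bool(state.clone_active),
        "scenario": _scenario_config_dict(state.scenario.config),
        "rng_state": state.rng.bit_generator.state,
    }
    (path / "meta.json").write_text(json.dumps(meta, default=int))


def read_snapshot(path):
    """Reconstruct a SimState from :func:`write_snapshot` output."""
    from .geometry import Disc
    from .runner import CloneSpec, ScenarioConfig, SimState, build_scenario

    path = pathlib.Path(path)
    for fname in ("cells.csv", "edges.csv", "bonds.csv", "meta.json"):
        if not (path / fname).exists():
            raise SchemaError(f"snapshot at {path} is missing {fname}")
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"snapshot schema {meta.get('schema_version')} != {SCHEMA_VERSION}")
    cells = pd.read_csv(path / "cells.csv", float_precision="round_trip")
    disc = Disc(cells[["x_um", "y_um"]].to_numpy(),
                cells["radius_um"].to_numpy(),
                dt=meta["dt"], step=meta["step"])
    disc.birth_step[:] = cells["birth_step"]
    disc.mother_id[:] = cells["mother_id"]
    disc.region[:] = cells["region"]
    disc.jitter = cells[["jitter_x", "jitter_y"]].to_numpy()
    for name in ("ft_u", "ft_p", "ds_u", "ds_p", "y_m", "y_ft", "y_ds"):
        getattr(disc, name)[:] = cells[name]
    disc.x_ft_raw[:] = cells["x_ft"]
    disc.x_ds_raw[:] = cells["x_ds"]
    disc.dachs = cells[["dachs_dx", "dachs_dy"]].to_numpy()
    disc.dachs_mag[:] = cells["dachs_magnitude"]
    graph = NeighborGraph(n_cells=disc.n_cells)
    e = pd.read_csv(path / "edges.csv")
    graph.est = {(int(a), int(b)): int(s) for a, b, s in
                 zip(e["cell_a"], e["cell_b"], e["established_step"])}
    bonds = BondTable.from_dataframe(pd.read_csv(path / "bonds.csv"))
    sdict = meta["scenario"]
    clone = CloneSpec(**sdict["clone"]) if sdict.get("clone") else None
    config = ScenarioConfig(genotype=sdict["genotype"],
                            front_mode=sdict["front_mode"], clone=clone,
                            overrides=sdict.get("overrides") or {})
    scenario = build_scenario(config)
    rng = np.random.default_rng()
    rng.bit_generator.state = meta["rng_state"]
    return SimState(disc=disc, graph=graph, bonds=bonds, scenario=scenario,
                    rng=rng, clone_active=meta["clone_active"])


def write_run_dir(record: RunRecord, path) -> None:
    """One self-contained directory per run: summary series, metadata,
    per-snapshot cell tables, and a resumable final state."""
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    record.summary.to_csv(path / "summary.csv", index=False)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "run_config": dataclasses.asdict(record.run_config),
        "scenario": _scenario_config_dict(record.scenario.config),
    }
    (path / "meta.json").write_text(json.dumps(meta, default=str))
    for step_idx, cells in record.snapshots.items():
        cells.to_csv(path / f"cells_{step_idx}.csv", index=False)
    if record.final_state is not None:
        write_snapshot(record.final_state, path / "state")
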