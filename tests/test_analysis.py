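import numpy as np
import pandas as pd
import pytest

from discsim import analysis
from discsim.analysis import (RunRecord, SchemaError, disc_size_comparison,
                              distal_alignment, polarization_map,
                              radial_profile)


def make_cells(pos, dachs=None, mag=None, **extra):
    pos = np.asarray(pos, float)
    n = len(pos)
    dachs = np.zeros((n, 2)) if dachs is None else np.asarray(dachs, float)
    mag = np.zeros(n) if mag is None else np.asarray(mag, float)
    centroid = pos.mean(axis=0)
    df = pd.DataFrame({
        "id": np.arange(n),
        "x_um": pos[:, 0], "y_um": pos[:, 1],
        "radial_um": np.hypot(*(pos - centroid).T),
        "dachs_dx": dachs[:, 0], "dachs_dy": dachs[:, 1],
        "dachs_magnitude": mag,
    })
    for k, v in extra.items():
        df[k] = v
    return df


def ring_positions(n, radius, rng=None):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(th), radius * np.sin(th)])


class TestRadialProfile:
    def test_uniform_quantity(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-10, 10, (300, 2))
        cells = make_cells(pos, q=np.ones(300))
        prof = radial_profile(cells, "q", n_bins=8)
        filled = prof.dropna()
        assert np.allclose(filled["mean"], 1.0)
        assert np.allclose(filled["sd"], 0.0)

    def test_radially_symmetric_field_recovered(self):
        """A synthetic field q = f(r) is reproduced within binning error."""
        rng = np.random.default_rng(1)
        r = 20 * np.sqrt(rng.random(4000))
        th = rng.uniform(0, 2 * np.pi, 4000)
        pos = np.column_stack([r * np.cos(th), r * np.sin(th)])
        cells = make_cells(pos, q=np.exp(-np.hypot(*(pos).T) / 10))
        prof = radial_profile(cells, "q", n_bins=10, R=20.0)
        expected = np.exp(-prof["bin_center"] / 10)
        assert np.nanmax(np.abs(prof["mean"] - expected)) < 0.05

    def test_empty_bins_missing_not_zero(self):
        cells = make_cells(ring_positions(50, 10.0), q=np.ones(50))
        prof = radial_profile(cells, "q", n_bins=10, R=12.0)
        assert prof["mean"].isna().any()
        assert not (prof["mean"].dropna() == 0).any()

    def test_unknown_quantity_lists_valid_names(self):
        cells = make_cells([[0, 0], [1, 1]], q=[1, 2])
        with pytest.raises(KeyError, match="valid"):
            radial_profile(cells, "nonesuch")


class TestPolarizationMap:
    def test_uniform_field(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(-15, 15, (500, 2))
        cells = make_cells(pos, dachs=np.tile([-1.0, 0.0], (500, 1)),
                           mag=np.full(500, 0.8))
        grid = polarization_map(cells, smoothing_radius=5.0, grid_spacing=5.0)
        assert len(grid) > 0
        assert np.allclose(grid["vx"], -0.8, atol=1e-12)
        assert np.allclose(grid["vy"], 0.0, atol=1e-12)
        assert np.allclose(grid["mean_magnitude"], 0.8)

    def test_random_directions_cancel_in_vector_mean(self):
        """Law of large numbers: isotropic directions give near-zero vector
        means while the scalar magnitude mean stays finite."""
        rng = np.random.default_rng(3)
        n = 4000
        th = rng.uniform(0, 2 * np.pi, n)
        pos = rng.uniform(-10, 10, (n, 2))
        cells = make_cells(pos, dachs=np.column_stack([np.cos(th), np.sin(th)]),
                           mag=np.ones(n))
        grid = polarization_map(cells, smoothing_radius=8.0, grid_spacing=8.0)
        vnorm = np.hypot(grid["vx"], grid["vy"])
        assert vnorm.mean() < 0.2
        assert grid["mean_magnitude"].mean() == pytest.approx(1.0)

    def test_vector_mean_bounded_by_scalar_mean(self, short_wildtype_state):
        cells = analysis.cells_dataframe(short_wildtype_state.disc)
        grid = polarization_map(cells)
        vnorm = np.hypot(grid["vx"], grid["vy"])
        assert np.all(vnorm <= grid["mean_magnitude"] + 1e-12)

    def test_empty_neighborhoods_omitted(self):
        cells = make_cells([[0.0, 0.0], [40.0, 0.0]], mag=[1.0, 1.0],
                           dachs=[[1, 0], [1, 0]])
        grid = polarization_map(cells, smoothing_radius=2.0, grid_spacing=4.0)
        # no grid point between the two far-apart cells reports a value
        mid = (grid["x_um"] > 10) & (grid["x_um"] < 30)
        assert not mid.any()


class TestDistalAlignment:
    def test_all_inward_is_one(self):
        pos = ring_positions(40, 10.0)
        inward = -pos / np.hypot(*pos.T)[:, None]
        cells = make_cells(pos, dachs=inward, mag=np.ones(40))
        assert distal_alignment(cells) == pytest.approx(1.0)

    def test_all_outward_is_minus_one(self):
        pos = ring_positions(40, 10.0)
        outward = pos / np.hypot(*pos.T)[:, None]
        cells = make_cells(pos, dachs=outward, mag=np.ones(40))
        assert distal_alignment(cells) == pytest.approx(-1.0)

    def test_isotropic_near_zero(self):
        rng = np.random.default_rng(4)
        n = 5000
        th = rng.uniform(0, 2 * np.pi, n)
        pos = rng.uniform(-10, 10, (n, 2))
        cells = make_cells(pos, dachs=np.column_stack([np.cos(th), np.sin(th)]),
                           mag=np.ones(n))
        assert abs(distal_alignment(cells)) < 3.0 / np.sqrt(n) * 2

    def test_zero_magnitude_cells_excluded(self):
        pos = ring_positions(10, 5.0)
        inward = -pos / np.hypot(*pos.T)[:, None]
        mag = np.ones(10)
        mag[5:] = 0.0
        outward = inward.copy()
        outward[5:] *= -1  # these would flip the mean if counted
        cells = make_cells(pos, dachs=outward, mag=mag)
        assert distal_alignment(cells) == pytest.approx(1.0)

    def test_empty_region_is_nan(self):
        cells = make_cells([[0, 0], [1, 0]], mag=[0.0, 0.0])
        assert np.isnan(distal_alignment(cells))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(-10, 10, (200, 2))
        th = rng.uniform(0, 2 * np.pi, 200)
        dachs = np.column_stack([np.cos(th), np.sin(th)])
        cells = make_cells(pos, dachs=dachs, mag=np.ones(200))
        a = distal_alignment(cells)
        phi = 0.7
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        cells2 = make_cells(pos @ rot.T, dachs=dachs @ rot.T, mag=np.ones(200))
        assert distal_alignment(cells2) == pytest.approx(a, abs=1e-9)


class TestDiscSizeComparison:
    def _record(self, n_cells, n_steps=100):
        rec = RunRecord()
        rec.summaries = [{"step": n_steps, "n_cells": n_cells}]
        return rec

    def test_wildtype_ratio_is_one(self):
        recs = {"wildtype": [self._record(1000), self._record(1100)]}
        table = disc_size_comparison(recs)
        assert table.loc[table["genotype"] == "wildtype",
                         "ratio_to_wildtype"].iloc[0] == pytest.approx(1.0)

    def test_ratios_and_sd(self):
        recs = {"wildtype": [self._record(1000)],
                "uniform_ds": [self._record(600), self._record(700)]}
        table = disc_size_comparison(recs).set_index("genotype")
        assert table.loc["uniform_ds", "ratio_to_wildtype"] == pytest.approx(0.65)
        assert table.loc["uniform_ds", "replicate_sd"] == pytest.approx(50.0)

    def test_mismatched_lengths_rejected(self):
        recs = {"wildtype": [self._record(1000, 100)],
                "uniform_ds": [self._record(800, 200)]}
        with pytest.raises(ValueError, match="lengths"):
            disc_size_comparison(recs)


class TestSnapshotIO:
    def test_roundtrip_equality(self, short_wildtype_state, tmp_path):
        st = short_wildtype_state
        analysis.write_snapshot(st, tmp_path / "s")
        st2 = analysis.read_snapshot(tmp_path / "s")
        assert np.array_equal(st.disc.pos, st2.disc.pos)
        assert np.array_equal(st.disc.ft_u, st2.disc.ft_u)
        assert st.graph.est == st2.graph.est
        assert st.bonds.total() == st2.bonds.total()
        assert st.rng.bit_generator.state == st2.rng.bit_generator.state

    def test_missing_bond_file_is_schema_error(self, short_wildtype_state,
                                               tmp_path):
        analysis.write_snapshot(short_wildtype_state, tmp_path / "s")
        (tmp_path / "s" / "bonds.csv").unlink()
        with pytest.raises(SchemaError, match="bonds.csv"):
            analysis.read_snapshot(tmp_path / "s")

    def test_schema_version_mismatch(self, short_wildtype_state, tmp_path):
        import json
        analysis.write_snapshot(short_wildtype_state, tmp_path / "s")
        meta = json.loads((tmp_path / "s" / "meta.json").read_text())
        meta["schema_version"] = 999
        (tmp_path / "s" / "meta.json").write_text(json.dumps(meta))
        with pytest.raises(SchemaError, match="schema"):
            analysis.read_snapshot(tmp_path / "s")
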