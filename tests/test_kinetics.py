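import numpy as np
import pytest

from discsim.kinetics import (BondTable, KineticParams, ProteinPools,
                              degrade_free, dephosphorylate, dissolve_bonds,
                              express_proteins, form_bonds,
                              form_bonds_expected, partition_free,
                              partition_free_all, pair_and_bind)


@pytest.fixture
def params():
    return KineticParams()


def single_pool(ft_u=0, ft_p=0, ds_u=0, ds_p=0):
    return ProteinPools(*(np.array([v], dtype=np.int64)
                          for v in (ft_u, ft_p, ds_u, ds_p)))


class TestExpression:
    def test_no_fj_means_no_phosphorylation(self, params, rng):
        p = single_pool()
        for _ in range(50):
            express_proteins(p, 0.0, 20.0, params, 1.0, rng)
        assert p.ft_p[0] == 0 and p.ds_p[0] == 0
        assert p.ft_u[0] > 0 and p.ds_u[0] > 0

    def test_half_saturating_fj_phosphorylates_half(self, params, rng):
        """At fj == phos_K new protein is phosphorylated with p = 1/2
        (binomial oracle, 3 sigma)."""
        p = ProteinPools.zeros(1)
        express_proteins(p, params.phos_K, 10000.0, params, 1.0, rng)
        n = p.ds_u[0] + p.ds_p[0]
        frac = p.ds_p[0] / n
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_mean_ds_production_rate(self, params, rng):
        p = ProteinPools.zeros(1)
        steps = 400
        for _ in range(steps):
            express_proteins(p, 0.0, 20.0, params, 1.0, rng, ft_rate=0.0)
        mean = (p.ds_u[0] + p.ds_p[0]) / steps
        assert abs(mean - 20.0) < 3 * np.sqrt(20.0 / steps)


class TestPartition:
    def test_even_split(self, rng):
        assert partition_free(12, 6, rng).tolist() == [2] * 6

    def test_remainder_rule(self, rng):
        alloc = partition_free(13, 6, rng)
        assert alloc.sum() == 13
        assert sorted(alloc.tolist()) == [2, 2, 2, 2, 2, 3]

    def test_zero_neighbors(self, rng):
        assert partition_free(7, 0, rng).size == 0

    def test_vectorised_matches_contract(self, rng):
        """The grouped engine partition obeys the same contract as the
        per-cell operation: exact sums and max spread 1 within each cell."""
        n_cells = 40
        pool = rng.integers(0, 200, n_cells)
        owner = np.repeat(np.arange(n_cells), rng.integers(1, 8, n_cells))
        rng2 = np.random.default_rng(0)
        alloc = partition_free_all(pool, owner, n_cells, rng2)
        for c in range(n_cells):
            a = alloc[owner == c]
            assert a.sum() == pool[c]
            assert a.max() - a.min() <= 1


class TestFormBonds:
    def test_no_ft_no_bonds(self, params, rng):
        bonds, lf, ld = form_bonds((0, 0), (50, 10), params.w, rng)
        assert bonds.sum() == 0
        assert ld.tolist() == [50, 10]

    def test_single_type_binomial_mean_phospho_ft(self, params):
        """100 FtP vs 100 Ds_u at weight 0.7: mean 70 bonds over 200
        seeded repeats (binomial oracle, 3 sigma)."""
        rng = np.random.default_rng(77)
        reps = 200
        tot = sum(form_bonds((0, 100), (100, 0), params.w, rng)[0][1]
                  for _ in range(reps))
        se = np.sqrt(100 * 0.7 * 0.3 / reps)
        assert abs(tot / reps - 70.0) < 3 * se

    def test_single_type_binomial_mean_phospho_ds(self, params):
        rng = np.random.default_rng(78)
        reps = 200
        tot = sum(form_bonds((100, 0), (0, 100), params.w, rng)[0][2]
                  for _ in range(reps))
        se = np.sqrt(100 * 0.05 * 0.95 / reps)
        assert abs(tot / reps - 5.0) < 3 * se

    def test_capacity_limits(self, params, rng):
        for _ in range(50):
            bonds, lf, ld = form_bonds((3, 5), (2, 4), params.w, rng)
            # per type, bonds cannot exceed either side's allocation
            assert bonds[0] + bonds[2] <= 3      # Ft_u used
            assert bonds[1] + bonds[3] <= 5      # Ft_p used
            assert bonds[0] + bonds[1] <= 2      # Ds_u used
            assert bonds[2] + bonds[3] <= 4      # Ds_p used
            assert bonds.sum() <= min(8, 6)
            assert (lf >= 0).all() and (ld >= 0).all()

    def test_expected_mode_single_type(self, params):
        assert form_bonds_expected((0, 100), (100, 0), params.w).tolist() == \
            [0, 70, 0, 0]

    def test_stochastic_mean_matches_expected_mode(self, params):
        rng = np.random.default_rng(5)
        reps = 300
        acc = np.zeros(4)
        for _ in range(reps):
            acc += pair_and_bind(40, 60, 30, 70, params.w, rng)
        exp = form_bonds_expected((40, 60), (30, 70), params.w)
        assert np.all(np.abs(acc / reps - exp) < 3.0)


class TestDissolveDegrade:
    def test_dissolution_mean(self, rng):
        """k = 0.08, dt = 1: a 100-bond ledger loses 8 per step on
        average (binomial oracle over many repeats)."""
        reps = 400
        lost = 0
        for _ in range(reps):
            remaining, released = dissolve_bonds(
                np.array([[100, 0, 0, 0]]), 0.08, 1.0, rng)
            lost += released.sum()
        se = np.sqrt(100 * 0.08 * 0.92 / reps)
        assert abs(lost / reps - 8.0) < 3 * se

    def test_zero_rate_noop(self, rng):
        counts = np.array([[3, 4, 5, 6]])
        remaining, released = dissolve_bonds(counts, 0.0, 1.0, rng)
        assert np.array_equal(remaining, counts)
        assert released.sum() == 0

    def test_release_conserves_per_state(self, rng):
        counts = np.array([[40, 30, 20, 10]])
        remaining, released = dissolve_bonds(counts, 0.5, 1.0, rng)
        assert np.array_equal(remaining + released, counts)

    def test_degradation_mean(self, rng):
        reps = 300
        lost = 0
        for _ in range(reps):
            p = single_pool(ds_u=1000)
            degrade_free(p, 0.08, 0.08, 1.0, rng)
            lost += 1000 - p.ds_u[0]
        se = np.sqrt(1000 * 0.08 * 0.92 / reps)
        assert abs(lost / reps - 80.0) < 3 * se

    def test_degradation_spares_bound_protein(self, rng):
        p = single_pool(ft_u=50, ft_p=60, ds_u=70, ds_p=80)
        bonds = BondTable()
        bonds.add(0, 1, [5, 6, 7, 8])
        degrade_free(p, 1.0, 1.0, 1.0, rng)
        assert p.total_ft()[0] == 0 and p.total_ds()[0] == 0
        assert bonds.total() == 26

    def test_dephosphorylation_conserves_totals(self, rng):
        p = single_pool(ft_p=100, ds_p=40, ft_u=7, ds_u=3)
        dephosphorylate(p, 0.1, 1.0, rng)
        assert p.total_ft()[0] == 107
        assert p.total_ds()[0] == 43
        assert p.ft_p[0] < 100  # some moved with overwhelming probability

    def test_dephosphorylation_mean(self, rng):
        reps = 300
        moved = 0
        for _ in range(reps):
            p = single_pool(ft_p=100)
            dephosphorylate(p, 0.1, 1.0, rng)
            moved += p.ft_u[0]
        se = np.sqrt(100 * 0.1 * 0.9 / reps)
        assert abs(moved / reps - 10.0) < 3 * se


class TestBondTable:
    def test_single_shared_ledger_is_symmetric(self):
        t = BondTable()
        t.add(3, 7, [1, 2, 3, 4])
        assert t.get(3, 7).sum() == 10
        # cell 3's bound Ft toward 7 == cell 7's bound Ds toward 3 by
        # construction (same row)
        assert t.bound_ft_per_cell(8)[3] == t.bound_ds_per_cell(8)[7] == 10

    def test_rekey_merges(self):
        t = BondTable()
        t.add(0, 2, [1, 0, 0, 0])
        t.add(1, 2, [0, 2, 0, 0])
        t.rekey(0, 2, 1, 2)
        assert t.get(1, 2).tolist() == [1, 2, 0, 0]
        assert t.get(0, 2).sum() == 0

    def test_roundtrip_dataframe(self):
        t = BondTable()
        t.add(0, 1, [1, 2, 3, 4])
        t.add(5, 2, [4, 0, 0, 1])
        t2 = BondTable.from_dataframe(t.to_dataframe())
        assert t2.get(5, 2).tolist() == [4, 0, 0, 1]
        assert t2.total() == t.total()


class TestEquilibrium:
    def test_isolated_cell_free_pool_birth_death_mean(self, params):
        """With no neighbours, the free pool fluctuates around
        rate / k_deg (closed-form birth-death equilibrium)."""
        rng = np.random.default_rng(10)
        p = ProteinPools.zeros(1)
        burn, samples = 200, 600
        vals = []
        for i in range(burn + samples):
            express_proteins(p, 0.0, 20.0, params, 1.0, rng)
            degrade_free(p, params.k_deg_ft, params.k_deg_ds, 1.0, rng)
            if i >= burn:
                vals.append(p.total_ds()[0])
        mean = np.mean(vals)
        # equilibrium between expression (before decay) and 8% decay
        expected = 20.0 * 0.92 / 0.08
        assert abs(mean - expected) < 0.1 * expected
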