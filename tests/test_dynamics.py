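import numpy as np
import pytest

from conftest import block_matrix, make_domains
from sctad.hic_io import ContactMatrix, DomainSet, domain_set_from_boundaries
from sctad import dynamics


def domains_from_bounds(bounds, n_bins=100):
    return domain_set_from_boundaries(bounds, n_bins)


class TestClassifyVariation:
    def test_identical_all_matched(self):
        d = domains_from_bounds([20, 40, 60, 80])
        assert dynamics.classify_variation(d, d) == ["matched"] * 5

    def test_merged(self):
        ens = domains_from_bounds([20, 40, 60, 80])
        cell = domains_from_bounds([20, 60, 80])   # lacks the boundary at 40
        got = dynamics.classify_variation(ens, cell)
        assert got[1] == "merged"

    def test_split(self):
        ens = domains_from_bounds([50])
        cell = domains_from_bounds([25, 50])       # cuts inside ensemble domain 1
        got = dynamics.classify_variation(ens, cell)
        assert "split" in got

    def test_shifted(self):
        ens = domains_from_bounds([30, 60])
        cell = domains_from_bounds([20, 45])       # [20,45) straddles boundary 30
        got = dynamics.classify_variation(ens, cell)
        assert got[1] == "shifted"

    def test_flank_tolerance(self):
        # 60-kb offset is within the 100-kb flanking region at 40-kb bins
        ens = domains_from_bounds([40])
        cell = domains_from_bounds([42])
        got = dynamics.classify_variation(ens, cell, flank_bp=100_000)
        assert got == ["matched", "matched"]

    def test_classes_exhaustive(self):
        ens = domains_from_bounds([20, 40, 60, 80])
        rng = np.random.default_rng(0)
        valid = {"matched", "merged", "split", "shifted", "other"}
        for _ in range(20):
            cell = domains_from_bounds(
                rng.choice(np.arange(1, 100), 5, replace=False))
            got = dynamics.classify_variation(ens, cell)
            assert len(got) == len(cell.domains)
            assert set(got) <= valid


def catalog_from_bounds(per_cell, n_bins=100, ensemble=None):
    cells = [domain_set_from_boundaries(b, n_bins) for b in per_cell]
    ens = (domain_set_from_boundaries(ensemble, n_bins)
           if ensemble is not None else None)
    return dynamics.build_catalog(cells, ens)


class TestBoundaryPopularity:
    def test_thresholds_and_sets(self):
        rng = np.random.default_rng(1)
        n_cells, n_bins = 150, 400
        ens_bounds = np.arange(10, 390, 10)
        per_cell = []
        for _ in range(n_cells):
            # most boundaries at 6% rate; boundary 10 always, boundary 20 never
            use = ens_bounds[rng.random(len(ens_bounds)) < 0.06]
            use = np.union1d(use, [10])
            use = np.setdiff1d(use, [20])
            per_cell.append(use)
        cat = catalog_from_bounds(per_cell, n_bins, ensemble=ens_bounds)
        res = dynamics.boundary_popularity(cat, hi=12, lo=6, seed=0)
        assert 10 in res["popular"]
        assert 20 in res["unpopular"]

    def test_all_boundaries_everywhere_extreme(self):
        bounds = list(range(10, 310, 10))
        cat = catalog_from_bounds([bounds] * 150, 400, ensemble=bounds)
        res = dynamics.boundary_popularity(cat, hi=12, lo=6, seed=0,
                                           p_null=0.06)
        assert set(res["popular"]) == set(bounds)
        assert res["p_value"] < 0.01

    def test_null_p_value_not_extreme(self):
        rng = np.random.default_rng(2)
        ens = np.arange(5, 395, 5)
        per_cell = [ens[rng.random(ens.size) < 0.06] for _ in range(150)]
        cat = catalog_from_bounds(per_cell, 400, ensemble=ens)
        res = dynamics.boundary_popularity(cat, seed=3)
        assert res["p_value"] > 0.001


class TestClassifyScsb:
    def test_single_cell_all_scsb1(self):
        cat = catalog_from_bounds([[15, 35, 55]], 100, ensemble=[55])
        got = dynamics.classify_scsb(cat, n_perm=5, seed=0)
        assert got["observed"]["scSB-1"] == 2      # 15 and 35; 55 is ensemble
        assert got["observed"]["scSB-2"] == got["observed"]["scSB-m"] == 0

    def test_shared_bin_is_scsb_m(self):
        cat = catalog_from_bounds([[15], [15, 40], [15]], 100, ensemble=[70])
        got = dynamics.classify_scsb(cat, n_perm=5, seed=0)
        assert got["observed"]["scSB-m"] == 1      # bin 15 in 3 cells
        assert got["observed"]["scSB-1"] == 1      # bin 40

    def test_random_boundaries_within_envelope(self):
        rng = np.random.default_rng(3)
        per_cell = [rng.choice(400, 8, replace=False) for _ in range(30)]
        cat = catalog_from_bounds(per_cell, 400, ensemble=[100, 200, 300])
        got = dynamics.classify_scsb(cat, n_perm=60, seed=4)
        for cls in ("scSB-1", "scSB-2", "scSB-m", "absent"):
            lo, hi = np.percentile(got["control"][cls], [0.5, 99.5])
            assert lo - 5 <= got["observed"][cls] <= hi + 5


class TestNestedUnnested:
    def test_sorted_by_cross_contacts(self):
        n = 500
        rng = np.random.default_rng(5)
        base = rng.random((n, n)) * 0.1
        F = np.triu(base) + np.triu(base, 1).T
        bounds = np.arange(10, 460, 10)          # 45 boundaries
        # give each boundary a distinct cross-contact level by rank
        for rank, b in enumerate(bounds):
            F[b - 5:b, b:b + 5] += rank * 0.5
            F[b:b + 5, b - 5:b] += rank * 0.5
        m = ContactMatrix("chr1", 40_000, (F + F.T) / 2)
        d = domain_set_from_boundaries(bounds, n)
        nested, unnested = dynamics.nested_unnested(d, m, n_top=10, n_drop=5)
        # lowest 5 dropped; next 10 are unnested; top 10 nested
        assert set(unnested) == set(bounds[5:15])
        assert set(nested) == set(bounds[-10:])

    def test_zero_cross_boundary_dropped_first(self):
        n = 300
        F = block_matrix(n, 20, enrichment=5.0) * 10
        bounds = np.arange(20, 300, 20)
        F[100:110, 90:100] = 0.0                  # sever contacts at boundary 100
        F[90:100, 100:110] = 0.0
        m = ContactMatrix("chr1", 40_000, (F + F.T) / 2)
        d = domain_set_from_boundaries(bounds, n)
        nested, unnested = dynamics.nested_unnested(d, m, n_top=5, n_drop=1)
        assert 100 not in set(nested) | set(unnested)

    def test_too_few_boundaries(self):
        d = domains_from_bounds([50])
        m = ContactMatrix("chr1", 40_000, np.ones((100, 100)))
        with pytest.raises(ValueError, match="not enough"):
            dynamics.nested_unnested(d, m)


class TestConditionSpecific:
    def test_exclusive_bins_lead_ranking(self):
        rng = np.random.default_rng(6)
        n_bins = 1_000
        a_only = np.arange(1, 11)
        per_a = [np.union1d(a_only, rng.choice(np.arange(10, n_bins), 20,
                                               replace=False))
                 for _ in range(30)]
        per_b = [rng.choice(np.arange(10, n_bins), 20, replace=False)
                 for _ in range(30)]
        cat_a = catalog_from_bounds(per_a, n_bins)
        cat_b = catalog_from_bounds(per_b, n_bins)
        a_spec, b_spec = dynamics.condition_specific_boundaries(cat_a, cat_b,
                                                                n_select=20)
        assert set(a_only) <= set(a_spec)

    def test_identical_groups_refused(self):
        per = [[10, 30], [10, 50]]
        cat = catalog_from_bounds(per, 100)
        with pytest.warns(UserWarning, match="constant"):
            a, b = dynamics.condition_specific_boundaries(cat, cat, 5)
        assert a.size == 0 and b.size == 0


class TestCellClassification:
    def _two_groups(self, n_per=5, n_bins=120):
        ga = domain_set_from_boundaries([20, 40, 60, 80, 100], n_bins)
        gb = domain_set_from_boundaries([10, 30, 50, 70, 90, 110], n_bins)
        cells = ([{"chr1": ga}] * n_per) + ([{"chr1": gb}] * n_per)
        labels = [0] * n_per + [1] * n_per
        return cells, labels

    def test_disjoint_groups_perfect_auc(self):
        cells, labels = self._two_groups()
        got = dynamics.cell_classification(cells, labels)
        assert got["auc"] == 1.0
        T = got["T"]
        assert np.allclose(T[:5, :5], 1.0) and np.allclose(T[5:, 5:], 1.0)

    def test_invariant_to_cell_order(self):
        cells, labels = self._two_groups()
        perm = [3, 7, 1, 9, 0, 5, 2, 8, 4, 6]
        got = dynamics.cell_classification([cells[i] for i in perm],
                                           [labels[i] for i in perm])
        assert got["auc"] == 1.0

    def test_missing_chromosome_gets_zero_sign(self):
        cells, labels = self._two_groups()
        cells = [dict(c) for c in cells]
        del cells[0]["chr1"]
        cells[0]["chr2"] = domain_set_from_boundaries([15], 40)
        for c in cells[1:]:
            c["chr2"] = domain_set_from_boundaries([15], 40)
        got = dynamics.cell_classification(cells, labels)
        assert got["S"][0, 0] == 0   # chr1 missing for cell 0

    def test_needs_two_cells(self):
        with pytest.raises(ValueError):
            dynamics.cell_classification([{"chr1": domains_from_bounds([5])}])


class TestInterIntraCorrelation:
    def _signal(self, domains, n_cells=40, n_bins=100, noise=0.0, seed=0):
        # block-constant latent signal per cell: independent level per domain
        rng = np.random.default_rng(seed)
        sig = np.empty((n_cells, n_bins))
        for c in range(n_cells):
            for (a, b) in domains.domains:
                sig[c, a:b] = rng.normal()
            sig[c] += rng.normal(0, noise, n_bins) if noise else 0.0
        return sig

    def test_constructed_signal_separates(self):
        d = domains_from_bounds([20, 40, 60, 80])
        sig = self._signal(d, noise=0.05)
        got = dynamics.inter_intra_correlation([d] * 40, sig, sep_bins=6)
        assert got["r_intra"] > 0.9
        assert got["r_inter"] < 0.5
        assert got["p_value"] < 0.01

    def test_shuffled_domains_no_difference(self):
        d = domains_from_bounds([20, 40, 60, 80])
        sig = self._signal(d, noise=0.05, seed=1)
        shuf = domains_from_bounds([7, 33, 52, 88])
        got = dynamics.inter_intra_correlation([shuf] * 40, sig, sep_bins=6)
        assert abs(got["r_intra"] - got["r_inter"]) < 0.35

    def test_default_separation_is_240kb(self):
        import inspect
        sig = inspect.signature(dynamics.inter_intra_correlation)
        assert sig.parameters["sep_bins"].default == 240_000 // 40_000


class TestCompartmentBoundaries:
    def test_sign_flips_selected(self):
        d = domains_from_bounds([20, 40, 60])
        score = np.ones(100)
        score[20:40] = -1.0        # flips at 20 and 40, not at 60
        got = dynamics.compartment_domain_boundaries(d, score)
        assert list(got) == [20, 40]

    def test_constant_track_empty(self):
        d = domains_from_bounds([20, 40])
        got = dynamics.compartment_domain_boundaries(d, np.ones(100))
        assert got.size == 0

    def test_missing_flank_skipped(self):
        d = domains_from_bounds([20, 40])
        score = np.ones(100)
        score[20:40] = -1.0
        score[19] = np.nan
        with pytest.warns(UserWarning, match="skipped"):
            got = dynamics.compartment_domain_boundaries(d, score)
        assert list(got) == [40]
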