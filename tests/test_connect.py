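"""Connectedness statistics: pairwise, summaries, identities, limits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import connekt as ck
from connekt.connect import ContrastError, UndefinedContrastError
from connekt.simdata import two_unit_design
from tests.conftest import make_system


def synthetic_pev_store(k_units=2, sizes=(3, 4), seed=0):
    """PSD synthetic PEV matrix with a unit index; no mixed model behind it."""
    rng = np.random.default_rng(seed)
    n = sum(sizes[:k_units])
    B = rng.standard_normal((n, n + 2))
    P = B @ B.T / (n + 2)
    index, start = {}, 0
    for i, s in enumerate(sizes[:k_units]):
        index[f"u{i+1}"] = np.arange(start, start + s)
        start += s
    return ck.PEVStore(PEV=P, individual_ids=[str(i) for i in range(n)], unit_index=index)


class TestContrastVector:
    def test_nonzero_sum_rejected(self):
        with pytest.raises(ContrastError, match="sum to zero"):
            ck.ContrastVector(np.array([0.5, 0.2, -0.5]))

    def test_zero_vector_rejected(self):
        with pytest.raises(ContrastError, match="zero"):
            ck.ContrastVector(np.zeros(4))

    def test_unit_pair_contrast_coefficients(self):
        store = synthetic_pev_store(sizes=(3, 4))
        x = ck.unit_contrast(store, "u1", "u2").x
        np.testing.assert_allclose(x[:3], 1 / 3)
        np.testing.assert_allclose(x[3:], -1 / 4)


class TestPEVD:
    def test_self_pair_is_zero(self, unit_only_system):
        _, store, _, _ = unit_only_system
        assert ck.pevd_pairwise(store, 2, 2) == 0.0

    def test_uncorrelated_pair_sums_variances(self):
        store = synthetic_pev_store()
        P = store.PEV.copy()
        P[0, 1] = P[1, 0] = 0.0
        store.PEV = P
        assert ck.pevd_pairwise(store, 0, 1) == pytest.approx(P[0, 0] + P[1, 1])

    def test_pairwise_equals_quadratic_form(self, unit_only_system):
        _, store, _, _ = unit_only_system
        d = np.zeros(store.PEV.shape[0])
        d[1], d[5] = 1.0, -1.0
        assert ck.pevd_pairwise(store, 1, 5) == pytest.approx(d @ store.PEV @ d)

    def test_grpave_seven_individual_hand_arithmetic(self):
        """2 units of sizes 3 and 4: block means worked by hand."""
        store = synthetic_pev_store(sizes=(3, 4), seed=3)
        P = store.PEV
        m11 = P[:3, :3].mean()
        m22 = P[3:, 3:].mean()
        m12 = P[:3, 3:].mean()
        res = ck.pevd_grpave(store)
        assert res.pair("u1", "u2") == pytest.approx(m11 + m22 - 2 * m12)

    def test_grpave_equals_contrast_for_unit_pairs(self, unit_only_system):
        _, store, _, _ = unit_only_system
        grp = ck.pevd_grpave(store)
        for a, ua in enumerate(store.unit_labels):
            for ub in store.unit_labels[a + 1 :]:
                x = ck.unit_contrast(store, ua, ub)
                assert abs(grp.pair(ua, ub) - ck.pevd_contrast(store, x)) < 1e-10

    def test_idave_matches_double_loop(self, unit_only_system):
        _, store, _, _ = unit_only_system
        res = ck.pevd_idave(store)
        ua, ub = store.unit_labels[0], store.unit_labels[1]
        brute = np.mean(
            [
                ck.pevd_pairwise(store, i, j)
                for i in store.unit_index[ua]
                for j in store.unit_index[ub]
            ]
        )
        assert res.pair(ua, ub) == pytest.approx(brute)

    def test_exchangeable_individuals(self):
        """PEV = a*I: every cross-unit pairwise PEVD is 2a."""
        store = synthetic_pev_store(sizes=(2, 3))
        store.PEV = 0.7 * np.eye(5)
        res = ck.pevd_idave(store)
        assert res.pair("u1", "u2") == pytest.approx(1.4)

    def test_singleton_units_collapse_summaries(self):
        store = synthetic_pev_store(sizes=(1, 1), seed=5)
        pair = ck.pevd_pairwise(store, 0, 1)
        assert ck.pevd_idave(store).pair("u1", "u2") == pytest.approx(pair)
        assert ck.pevd_grpave(store).pair("u1", "u2") == pytest.approx(pair)

    def test_contrast_sign_flip_invariant(self, unit_only_system):
        _, store, _, _ = unit_only_system
        x = ck.unit_contrast(store, store.unit_labels[0], store.unit_labels[1])
        flipped = ck.ContrastVector(-x.x)
        assert ck.pevd_contrast(store, x) == pytest.approx(ck.pevd_contrast(store, flipped))


class TestCD:
    def test_no_information_limit_is_zero(self, toy_phenotypes):
        d = ck.build_design(toy_phenotypes, list("abcd"))
        vc = ck.VarianceComponents(sigma2_u=1.0, sigma2_e=1e8)
        system = ck.build_mme(d, np.eye(4), vc)
        store = ck.pev(system)
        K = ck.RelationshipMatrix(np.eye(4), list("abcd"))
        assert abs(ck.cd_pairwise(store, K, vc, 0, 2)) < 1e-4

    def test_perfect_information_limit_is_one(self):
        """lambda -> 0 with many records per unit: CD -> 1.

        With a unit fixed effect, each breeding value stays confounded with its
        unit mean, leaving CD at 1 - O(1/n) even with no residual noise; 50
        records per unit bring it within the 0.05 band.
        """
        n_per = 50
        ids = [f"i{k}" for k in range(2 * n_per)]
        pt = ck.PhenotypeTable(
            pd.DataFrame(
                {
                    "id": ids,
                    "unit": ["u1"] * n_per + ["u2"] * n_per,
                    "phenotype": np.zeros(2 * n_per),
                }
            )
        )
        d = ck.build_design(pt, ids)
        vc = ck.VarianceComponents(sigma2_u=1.0, sigma2_e=1e-8)
        system = ck.build_mme(d, np.eye(2 * n_per), vc)
        store = ck.pev(system)
        K = ck.RelationshipMatrix(np.eye(2 * n_per), ids)
        assert ck.cd_pairwise(store, K, vc, 0, n_per) == pytest.approx(1.0, abs=0.05)

    def test_pairwise_equals_quadratic_form_oracle(self, unit_only_system):
        _, store, A, vc = unit_only_system
        d = np.zeros(A.n)
        d[0], d[7] = 1.0, -1.0
        expected = 1.0 - (d @ store.PEV @ d) / (vc.sigma2_u * (d @ A.K @ d))
        assert ck.cd_pairwise(store, A, vc, 0, 7) == pytest.approx(expected)

    def test_identical_pair_is_undefined(self):
        store = synthetic_pev_store(sizes=(2, 2))
        K = ck.RelationshipMatrix(np.ones((4, 4)), [str(i) for i in range(4)])
        vc = ck.VarianceComponents.from_h2(0.5)
        with pytest.raises(UndefinedContrastError, match="identical"):
            ck.cd_pairwise(store, K, vc, 0, 1)

    def test_grpave_equals_contrast(self, unit_only_system):
        _, store, A, vc = unit_only_system
        grp = ck.cd_grpave(store, A, vc)
        con = ck.cd_contrast_pairs(store, A, vc)
        assert np.nanmax(np.abs(grp.matrix - con.matrix)) < 1e-10

    def test_grpave_identity_K_block_means(self):
        """K = I, units of sizes 3 and 4: block means are 1/3, 1/4, 0."""
        store = synthetic_pev_store(sizes=(3, 4), seed=2)
        P = store.PEV.copy()
        P[:3, 3:] = 0.0
        P[3:, :3] = 0.0
        store.PEV = P
        K = ck.RelationshipMatrix(np.eye(7), [str(i) for i in range(7)])
        vc = ck.VarianceComponents.from_h2(0.5)
        res = ck.cd_grpave(store, K, vc)
        pevd = ck.pevd_grpave(store).pair("u1", "u2")
        denom = vc.sigma2_u * (1 / 3 + 1 / 4 - 0)
        assert res.pair("u1", "u2") == pytest.approx(1 - pevd / denom)

    def test_idave_is_ratio_of_sums_not_mean_of_cds(self, unit_only_system):
        _, store, A, vc = unit_only_system
        ua, ub = store.unit_labels[0], store.unit_labels[1]
        ia, ib = store.unit_index[ua], store.unit_index[ub]
        pevd_sum = sum(ck.pevd_pairwise(store, i, j) for i in ia for j in ib)
        kdiff_sum = sum(
            A.K[i, i] + A.K[j, j] - 2 * A.K[i, j] for i in ia for j in ib
        )
        expected = 1.0 - pevd_sum / (vc.sigma2_u * kdiff_sum)
        res = ck.cd_idave(store, A, vc)
        assert res.pair(ua, ub) == pytest.approx(expected, abs=1e-12)
        naive = np.mean(
            [ck.cd_pairwise(store, A, vc, i, j) for i in ia for j in ib]
        )
        assert abs(res.pair(ua, ub) - naive) > 1e-6  # the two conventions differ

    def test_idave_constant_pairs_collapse_to_pairwise(self):
        store = synthetic_pev_store(sizes=(2, 2))
        store.PEV = 0.3 * np.eye(4)
        K = ck.RelationshipMatrix(np.eye(4), [str(i) for i in range(4)])
        vc = ck.VarianceComponents.from_h2(0.5)
        res = ck.cd_idave(store, K, vc)
        assert res.pair("u1", "u2") == pytest.approx(
            ck.cd_pairwise(store, K, vc, 0, 2)
        )

    def test_contrast_sign_flip_invariant(self, unit_only_system):
        _, store, A, vc = unit_only_system
        x = ck.unit_contrast(store, store.unit_labels[0], store.unit_labels[1])
        flipped = ck.ContrastVector(-x.x)
        assert ck.cd_contrast(store, A, vc, x) == pytest.approx(
            ck.cd_contrast(store, A, vc, flipped)
        )


class TestR:
    def test_self_correlation_is_one(self, unit_only_system):
        _, store, _, _ = unit_only_system
        assert ck.r_pairwise(store, 3, 3) == pytest.approx(1.0)

    def test_zero_covariance_gives_zero(self):
        store = synthetic_pev_store(sizes=(2, 2))
        store.PEV = np.diag([0.2, 0.3, 0.4, 0.5])
        assert ck.r_pairwise(store, 0, 2) == 0.0
        assert ck.r_idave(store).pair("u1", "u2") == 0.0

    def test_pairwise_matches_elementwise_formula(self, unit_only_system):
        _, store, _, _ = unit_only_system
        P = store.PEV
        expected = P[2, 9] / np.sqrt(P[2, 2] * P[9, 9])
        assert ck.r_pairwise(store, 2, 9) == pytest.approx(expected)
        assert -1.0 <= ck.r_pairwise(store, 2, 9) <= 1.0

    def test_grpave_blockmean_oracle(self, unit_only_system):
        _, store, _, _ = unit_only_system
        bm = ck.block_means(store)
        res = ck.r_grpave(store)
        ua, ub = store.unit_labels[0], store.unit_labels[2]
        a, b = 0, 2
        assert res.pair(ua, ub) == pytest.approx(bm[a, b] / np.sqrt(bm[a, a] * bm[b, b]))

    def test_grpave_identical_blocks_give_one(self):
        store = synthetic_pev_store(sizes=(3, 3), seed=7)
        block = store.PEV[:3, :3]
        store.PEV = np.block([[block, block], [block, block]])
        assert ck.r_grpave(store).pair("u1", "u2") == pytest.approx(1.0)

    def test_idave_double_loop_oracle(self, unit_only_system):
        _, store, _, _ = unit_only_system
        ua, ub = store.unit_labels[0], store.unit_labels[1]
        brute = np.mean(
            [
                ck.r_pairwise(store, i, j)
                for i in store.unit_index[ua]
                for j in store.unit_index[ub]
            ]
        )
        assert ck.r_idave(store).pair(ua, ub) == pytest.approx(brute)

    def test_contrast_identity_r_matrix(self):
        """r matrix = I: x' I x = 1/n1 + 1/n2 for a unit-pair contrast."""
        store = synthetic_pev_store(sizes=(3, 4))
        store.PEV = np.eye(7) * 0.4  # r matrix becomes exactly I
        x = ck.unit_contrast(store, "u1", "u2")
        assert ck.r_contrast(store, x) == pytest.approx(1 / 3 + 1 / 4)

    def test_contrast_quadratic_form_oracle(self, unit_only_system):
        _, store, _, _ = unit_only_system
        x = ck.unit_contrast(store, store.unit_labels[0], store.unit_labels[1])
        R = ck.r_matrix(store)
        assert ck.r_contrast(store, x) == pytest.approx(x.x @ R @ x.x)


class TestVEBridge:
    """VE-based statistics coincide with PEV group averages after correction."""

    def test_unit_only_correction_one(self, unit_only_system):
        system, store, A, vc = unit_only_system
        v1 = ck.ve1(system)
        assert np.abs(ck.ved(v1).matrix - ck.pevd_grpave(store).matrix).max() < 1e-8
        assert (
            np.nanmax(
                np.abs(
                    ck.cdved(v1, A, vc, store.unit_index).matrix
                    - ck.cd_grpave(store, A, vc).matrix
                )
            )
            < 1e-8
        )
        assert np.nanmax(np.abs(ck.cr(v1).matrix - ck.r_grpave(store).matrix)) < 1e-8

    def test_unit_sex_correction_two(self, unit_sex_system):
        system, store, A, vc = unit_sex_system
        v2 = ck.ve2(system)
        assert np.abs(ck.ved(v2).matrix - ck.pevd_grpave(store).matrix).max() < 1e-8
        assert (
            np.nanmax(
                np.abs(
                    ck.cdved(v2, A, vc, store.unit_index).matrix
                    - ck.cd_grpave(store, A, vc).matrix
                )
            )
            < 1e-8
        )
        assert np.nanmax(np.abs(ck.cr(v2).matrix - ck.r_grpave(store).matrix)) < 1e-8

    def test_ved_c0_minus_c1_is_record_correction(self, unit_only_system):
        system, _, _, vc = unit_only_system
        d0 = ck.ved(ck.ve0(system)).matrix
        d1 = ck.ved(ck.ve1(system)).matrix
        n = system.design.n_per_unit
        expected = vc.sigma2_e * (1 / n[:, None] + 1 / n[None, :])
        np.fill_diagonal(expected, 0.0)
        off = ~np.eye(len(n), dtype=bool)
        np.testing.assert_allclose((d0 - d1)[off], expected[off], atol=1e-10)

    def test_ved_self_pair_is_zero(self, unit_only_system):
        system, _, _, _ = unit_only_system
        assert np.abs(np.diag(ck.ved(ck.ve1(system)).matrix)).max() == 0.0

    def test_cdved_identical_rows_give_one(self):
        VE = np.full((3, 3), 0.2)
        v = ck.VEStore(VE=VE, unit_labels=["u1", "u2", "u3"], correction=0)
        K = ck.RelationshipMatrix(np.eye(6), [str(i) for i in range(6)])
        idx = {"u1": np.array([0, 1]), "u2": np.array([2, 3]), "u3": np.array([4, 5])}
        vc = ck.VarianceComponents.from_h2(0.5)
        res = ck.cdved(v, K, vc, idx)
        assert res.pair("u1", "u2") == pytest.approx(1.0)

    def test_cr_trivial_cases(self):
        VE = np.array([[0.2, 0.2], [0.2, 0.2]])
        v = ck.VEStore(VE=VE, unit_labels=["u1", "u2"], correction=0)
        assert ck.cr(v).pair("u1", "u2") == pytest.approx(1.0)
        v0 = ck.VEStore(np.diag([0.2, 0.3]), ["u1", "u2"], correction=0)
        assert ck.cr(v0).pair("u1", "u2") == 0.0


class TestOverall:
    def test_two_units_equals_single_pair(self, unit_only_system):
        system, store, _, _ = unit_only_system
        res = ck.pevd_grpave(store)
        two = ck.UnitPairResult(
            "PEVD", "GrpAve", None, res.matrix[:2, :2], res.unit_labels[:2]
        )
        assert ck.overall(two) == pytest.approx(two.matrix[0, 1])

    def test_constant_matrix(self):
        mat = np.full((3, 3), 0.4)
        res = ck.UnitPairResult("r", "GrpAve", None, mat, ["a", "b", "c"])
        assert ck.overall(res) == pytest.approx(0.4)

    def test_three_units_mean_of_three_pairs(self, unit_only_system):
        _, store, _, _ = unit_only_system
        res = ck.pevd_grpave(store)
        m = res.matrix
        assert ck.overall(res) == pytest.approx((m[0, 1] + m[0, 2] + m[1, 2]) / 3)


class TestStructuralProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_grpave_contrast_identity_across_seeds(self, seed):
        system, store, A, vc = make_system(seed=seed + 100, n_founders=8, offspring=16)
        assert (
            np.abs(ck.pevd_grpave(store).matrix - ck.pevd_contrast_pairs(store).matrix).max()
            < 1e-10
        )
        assert (
            np.nanmax(
                np.abs(ck.cd_grpave(store, A, vc).matrix - ck.cd_contrast_pairs(store, A, vc).matrix)
            )
            < 1e-10
        )

    def test_disconnected_units_have_zero_r(self):
        """Block-diagonal K and no shared fixed effects: cross-unit PEC = 0."""
        ped, units = two_unit_design(n_links=0)
        A = ck.build_A(ped)
        rng = np.random.default_rng(0)
        pt = ck.PhenotypeTable(
            pd.DataFrame(
                {"id": ped.ids, "unit": units, "phenotype": rng.standard_normal(len(units))}
            )
        )
        vc = ck.VarianceComponents.from_h2(0.5)
        Kinv, _ = ck.regularize_and_invert(A)
        system = ck.build_mme(ck.build_design(pt, A.individual_ids), Kinv, vc)
        store = ck.pev(system)
        assert abs(ck.r_grpave(store).pair("u1", "u2")) < 1e-10

    def test_connectedness_monotone_in_across_unit_links(self):
        """More shared sires: r and CD rise, PEVD falls, over a 0/2/4/8 ladder."""
        vc = ck.VarianceComponents.from_h2(0.5)
        rng = np.random.default_rng(11)
        rs, cds, pevds = [], [], []
        for n_links in (0, 2, 4, 8):
            ped, units = two_unit_design(n_links=n_links)
            A = ck.build_A(ped)
            pt = ck.PhenotypeTable(
                pd.DataFrame(
                    {"id": ped.ids, "unit": units, "phenotype": rng.standard_normal(len(units))}
                )
            )
            Kinv, _ = ck.regularize_and_invert(A)
            system = ck.build_mme(ck.build_design(pt, A.individual_ids), Kinv, vc)
            store = ck.pev(system)
            rs.append(ck.r_grpave(store).pair("u1", "u2"))
            cds.append(ck.cd_grpave(store, A, vc).pair("u1", "u2"))
            pevds.append(ck.pevd_grpave(store).pair("u1", "u2"))
        assert all(a < b for a, b in zip(rs, rs[1:]))
        assert all(a < b for a, b in zip(cds, cds[1:]))
        assert all(a > b for a, b in zip(pevds, pevds[1:]))

    def test_statistics_invariant_to_within_unit_relabeling(self):
        system, store, A, vc = make_system(seed=77, n_founders=8, offspring=16)
        # permute individuals globally and recompute through the same pipeline
        rng = np.random.default_rng(77)
        n = A.n
        perm = rng.permutation(n)
        K_perm = ck.RelationshipMatrix(
            A.K[np.ix_(perm, perm)], [A.individual_ids[p] for p in perm]
        )
        f = system.design
        pt = ck.PhenotypeTable(
            pd.DataFrame({"id": f.record_ids, "unit": [
                next(u for u, idx in store.unit_index.items()
                     if f.individual_ids.index(r) in idx)
                for r in f.record_ids
            ], "phenotype": f.y})
        )
        Kinv, _ = ck.regularize_and_invert(K_perm)
        system2 = ck.build_mme(
            ck.build_design(pt, K_perm.individual_ids), Kinv, vc
        )
        store2 = ck.pev(system2)
        np.testing.assert_allclose(
            ck.pevd_grpave(store).matrix, ck.pevd_grpave(store2).matrix, atol=1e-9
        )
        np.testing.assert_allclose(
            ck.r_idave(store).matrix, ck.r_idave(store2).matrix, atol=1e-9
        )


@settings(deadline=None, max_examples=30)
@given(
    n1=st.integers(1, 6),
    n2=st.integers(1, 6),
    seed=st.integers(0, 1000),
)
def test_unit_pair_contrast_always_sums_to_zero(n1, n2, seed):
    store = synthetic_pev_store(sizes=(n1, n2), seed=seed)
    x = ck.unit_contrast(store, "u1", "u2")
    assert abs(x.x.sum()) < 1e-12
    # quadratic form equals the group-average PEVD entry (identity)
    assert ck.pevd_contrast(store, x) == pytest.approx(
        ck.pevd_grpave(store).pair("u1", "u2"), abs=1e-10
    )
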