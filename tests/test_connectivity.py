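"""Fisher-z aggregation, group means/differences, mixed models, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cytoconn import connectivity as conn
from cytoconn.connectivity import ConnectivityMatrix, SystemDefinition


def _matrix(r, names=None, **meta):
    r = np.asarray(r, dtype=float)
    names = names or [f"n{i}" for i in range(r.shape[0])]
    return ConnectivityMatrix(r, names, metadata=meta)


def _uniform_matrix(n, val, **meta):
    r = np.full((n, n), val)
    np.fill_diagonal(r, 1.0)
    return _matrix(r, **meta)


class TestFisherZ:
    def test_zero_fixed_point(self):
        assert conn.fisher_z(0.0) == 0.0

    def test_half_closed_form(self):
        assert conn.fisher_z(0.5) == pytest.approx(0.5493, abs=5e-5)

    @given(st.floats(-0.999, 0.999))
    def test_round_trip(self, r):
        assert conn.inv_fisher_z(conn.fisher_z(r)) == pytest.approx(r, abs=1e-12)

    def test_unit_r_clipped_finite(self):
        assert np.isfinite(conn.fisher_z(1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            conn.fisher_z(1.5)


class TestAggregateSystem:
    def _two_system(self, r):
        sysdef = SystemDefinition({"A": ["n0", "n1"], "B": ["n2", "n3"]})
        return _matrix(r), sysdef

    def test_identical_values_pass_through(self):
        m = _uniform_matrix(4, 0.4)
        sysdef = SystemDefinition({"A": ["n0", "n1"], "B": ["n2", "n3"]})
        out = conn.aggregate_system(m, sysdef)
        assert np.allclose(out.to_numpy(), 0.4, atol=1e-12)

    def test_antisymmetric_pair_cancels(self):
        r = np.eye(4)
        r[0, 2] = r[2, 0] = 0.2
        r[0, 3] = r[3, 0] = -0.2
        r[1, 2] = r[2, 1] = 0.2
        r[1, 3] = r[3, 1] = -0.2
        m, sysdef = self._two_system(r)
        out = conn.aggregate_system(m, sysdef)
        assert out.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)

    def test_z_space_mean_exceeds_arithmetic(self):
        # {0.1, 0.5, 0.9}: tanh(mean(arctanh)) = 0.5800... > 0.5
        vals = [0.1, 0.5, 0.9]
        r = np.eye(3)
        r[0, 1] = r[1, 0] = vals[0]
        r[0, 2] = r[2, 0] = vals[1]
        r[1, 2] = r[2, 1] = vals[2]
        m = _matrix(r)
        sysdef = SystemDefinition({"A": ["n0", "n1", "n2"]})
        out = conn.aggregate_system(m, sysdef)
        expected = np.tanh(np.mean(np.arctanh(vals)))
        assert out.loc["A", "A"] == pytest.approx(expected, abs=1e-12)
        assert out.loc["A", "A"] > np.mean(vals)

    def test_roi_order_invariance(self, rng):
        n = 6
        u = rng.uniform(-0.5, 0.8, size=(n, n))
        r = np.triu(u, 1) + np.triu(u, 1).T + np.eye(n)
        names = [f"n{i}" for i in range(n)]
        m = ConnectivityMatrix(r, names)
        sysdef = SystemDefinition({"A": names[:3], "B": names[3:]})
        perm = rng.permutation(n)
        m2 = ConnectivityMatrix(r[np.ix_(perm, perm)],
                                [names[i] for i in perm])
        out1 = conn.aggregate_system(m, sysdef)
        out2 = conn.aggregate_system(m2, sysdef)
        np.testing.assert_allclose(out1.to_numpy(), out2.to_numpy(), atol=1e-12)

    def test_singleton_system_intra_rejected(self):
        m = _uniform_matrix(3, 0.2)
        sysdef = SystemDefinition({"A": ["n0"], "B": ["n1", "n2"]})
        with pytest.raises(ValueError, match="< 2 ROIs"):
            conn.aggregate_system(m, sysdef)

    def test_overlapping_systems_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SystemDefinition({"A": ["n0", "n1"], "B": ["n1", "n2"]})


class TestGroupMeanAndDifference:
    def test_identical_matrices_mean_is_identity(self):
        ms = [_uniform_matrix(3, 0.3) for _ in range(4)]
        out = conn.group_mean_matrix(ms)
        assert np.allclose(out.r[0, 1], 0.3, atol=1e-12)

    def test_antisymmetric_pair_means_zero(self):
        out = conn.group_mean_matrix(
            [_uniform_matrix(3, 0.2), _uniform_matrix(3, -0.2)])
        assert out.r[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_mixed_values_use_z_mean(self):
        out = conn.group_mean_matrix(
            [_uniform_matrix(3, 0.1), _uniform_matrix(3, 0.9)])
        expected = np.tanh(0.5 * (np.arctanh(0.1) + np.arctanh(0.9)))
        assert out.r[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            conn.group_mean_matrix([])

    def test_difference_identity_is_zero(self):
        a = _uniform_matrix(3, 0.4)
        assert np.allclose(conn.difference_matrix(a, a).to_numpy(), 0.0)

    def test_difference_closed_form(self):
        d = conn.difference_matrix(_uniform_matrix(3, 0.5),
                                   _uniform_matrix(3, 0.0))
        assert d.iloc[0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-12)

    def test_difference_antisymmetry(self, rng):
        a = _uniform_matrix(3, 0.35)
        b = _uniform_matrix(3, -0.1)
        np.testing.assert_allclose(conn.difference_matrix(a, b).to_numpy(),
                                   -conn.difference_matrix(b, a).to_numpy(),
                                   atol=1e-12)

    def test_group_mean_then_difference_linear_in_z(self, rng):
        groups = {}
        for g, shift in (("5xFAD", -0.1), ("WT", 0.1)):
            mats = []
            for _ in range(5):
                u = rng.uniform(-0.3, 0.5, size=(4, 4)) + shift
                r = np.triu(u, 1) + np.triu(u, 1).T + np.eye(4)
                mats.append(_matrix(np.clip(r, -0.99, 0.99)))
            groups[g] = mats
        means = {g: conn.group_mean_matrix(ms) for g, ms in groups.items()}
        d1 = conn.difference_matrix(means["5xFAD"], means["WT"]).to_numpy()
        z_direct = (np.mean([conn.fisher_z(m.r) for m in groups["5xFAD"]], axis=0)
                    - np.mean([conn.fisher_z(m.r) for m in groups["WT"]], axis=0))
        np.fill_diagonal(z_direct, 0.0)
        np.testing.assert_allclose(d1, z_direct, atol=1e-10)


def _edge_table_from_values(values):
    """values: dict (genotype, subject) -> list of per-scan y for one edge."""
    rows = []
    for (g, s), ys in values.items():
        for i, y in enumerate(ys):
            rows.append({"roi_i": "a", "roi_j": "b", "y": y, "subject": s,
                         "genotype": g, "age_months": 6.0, "scan_id": i})
    return pd.DataFrame(rows)


class TestEdgewiseLME:
    def test_zero_subject_variance_matches_group_mean_difference(self, rng):
        values = {}
        for g in ("5xFAD", "WT"):
            for s in range(6):
                mu = 0.5 if g == "5xFAD" else 0.2
                values[(g, f"{g}{s}")] = list(mu + rng.normal(0, 0.05, 3))
        table = _edge_table_from_values(values)
        stats = conn.fit_edgewise_lme(table)
        fad = table[table.genotype == "5xFAD"]["y"].mean()
        wt = table[table.genotype == "WT"]["y"].mean()
        assert stats.table["beta"].iloc[0] == pytest.approx(fad - wt, abs=1e-5)

    def test_type_one_error_calibrated(self, rng):
        # 200 independent null edges, balanced design with subject effects
        n_sig = 0
        for e in range(200):
            values = {}
            for g in ("5xFAD", "WT"):
                for s in range(8):
                    u = rng.normal(0, 0.1)
                    values[(g, f"{g}{s}")] = list(u + rng.normal(0, 0.1, 2))
            stats = conn.fit_edgewise_lme(_edge_table_from_values(values))
            n_sig += int(stats.table["p"].iloc[0] < 0.05)
        assert 0.02 <= n_sig / 200 <= 0.09

    def test_power_at_planted_effect(self, rng):
        # effect = 1.5 x residual SD, n = 10 subjects/group
        n_rej = 0
        for e in range(200):
            values = {}
            for g in ("5xFAD", "WT"):
                mu = 0.15 if g == "5xFAD" else 0.0
                for s in range(10):
                    u = rng.normal(0, 0.05)
                    values[(g, f"{g}{s}")] = list(mu + u + rng.normal(0, 0.1, 2))
            stats = conn.fit_edgewise_lme(_edge_table_from_values(values))
            n_rej += int(stats.table["p"].iloc[0] < 0.05)
        assert n_rej / 200 >= 0.8

    def test_longitudinal_interaction_detected(self, rng):
        # genotype effect grows with age: interaction coefficient significant
        rows = []
        for g in ("5xFAD", "WT"):
            for s in range(8):
                u = rng.normal(0, 0.03)
                for age in (1.5, 2.0, 4.0, 6.0):
                    slope = -0.08 if g == "5xFAD" else 0.0
                    y = 0.4 + u + slope * age + rng.normal(0, 0.05)
                    rows.append({"roi_i": "a", "roi_j": "b", "y": y,
                                 "subject": f"{g}{s}", "genotype": g,
                                 "age_months": age, "scan_id": 0})
        stats = conn.fit_edgewise_lme(pd.DataFrame(rows), longitudinal=True,
                                      term="genotype:age")
        assert stats.table["p"].iloc[0] < 0.01
        assert stats.table["beta"].iloc[0] < 0

    def test_requires_two_subjects_per_genotype(self):
        table = _edge_table_from_values({("5xFAD", "f1"): [0.1, 0.2],
                                         ("WT", "w1"): [0.0, 0.1],
                                         ("WT", "w2"): [0.2, 0.1]})
        with pytest.raises(ValueError, match="2 subjects"):
            conn.fit_edgewise_lme(table)


class TestGlobalMetricAnova:
    def _table(self, rng, interaction=0.0):
        rows = []
        for g in ("5xFAD", "WT"):
            for s in range(8):
                for age in (1.5, 2.0, 4.0, 6.0):
                    y = (3.0 + rng.normal(0, 0.3)
                         + (interaction * age if g == "5xFAD" else 0.0))
                    rows.append({"subject": f"{g}{s}", "genotype": g,
                                 "age_months": age, "value": y})
        return pd.DataFrame(rows)

    def test_null_interaction_not_significant(self, rng):
        table = conn.anova_genotype_by_age(self._table(rng))
        assert table.loc["genotype:age", "PR(>F)"] > 0.01

    def test_planted_interaction_detected(self, rng):
        table = conn.anova_genotype_by_age(self._table(rng, interaction=0.3))
        assert table.loc["genotype:age", "PR(>F)"] < 0.001
        assert set(table.index) >= {"genotype", "age", "genotype:age"}


class TestFDR:
    def test_hand_computed_bh(self):
        q = conn.fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_all_ones(self):
        q = conn.fdr_correct(np.ones(5))
        np.testing.assert_allclose(q, 1.0)
        assert not conn.binarize(q).any()

    def test_single_p_passthrough(self):
        np.testing.assert_allclose(conn.fdr_correct(np.array([0.037])), [0.037])

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=30)
        q = conn.fdr_correct(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            conn.fdr_correct(np.array([0.5, 1.2]))
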