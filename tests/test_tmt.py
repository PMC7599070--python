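"""Z-score normalisation, treatment deltas and the Welch comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import holophos as hp


def welch_oracle(a, b):
    """Textbook Welch t statistic and two-sided p."""
    from scipy.stats import t as t_dist
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2 * t_dist.sf(abs(t), df)


class TestZscoreNormalize:
    def test_simple_column(self):
        m = pd.DataFrame({"s1": [1.0, 2.0, 3.0]})
        out = hp.zscore_normalize(m)
        assert out["s1"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(50, 4)),
                         columns=list("abcd"))
        once = hp.zscore_normalize(m)
        twice = hp.zscore_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_missing_preserved_and_ignored(self):
        m = pd.DataFrame({"s1": [1.0, np.nan, 3.0]})
        out = hp.zscore_normalize(m)
        assert np.isnan(out["s1"][1])
        present = out["s1"].dropna()
        assert present.mean() == pytest.approx(0.0)
        assert present.std(ddof=1) == pytest.approx(1.0)

    def test_constant_column_names_sample(self):
        m = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            hp.zscore_normalize(m)

    def test_output_columns_standardised(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(3.0, 2.5, size=(100, 6)))
        out = hp.zscore_normalize(m)
        assert np.allclose(out.mean(), 0.0, atol=1e-9)
        assert np.allclose(out.std(ddof=1), 1.0, atol=1e-9)


class TestTreatmentDeltas:
    def _setup(self, drop=None):
        design = hp.default_tmt_design(replicates=2, regions=("cortical",),
                                       ms_modes=("MS2",))
        table = design.table
        if drop:
            design = hp.TmtDesign(table.drop(index=drop))
            table = design.table
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(10, len(table))),
                         index=[f"s{i}" for i in range(10)],
                         columns=table.index)
        return m, design

    def test_identical_treatment_columns_give_zero(self):
        m, design = self._setup()
        for g in ("WT", "KO"):
            for rep in (1, 2):
                m[f"{g}_CD_r{rep}_cortical_MS2"] = \
                    m[f"{g}_DMSO_r{rep}_cortical_MS2"]
        deltas, warnings = hp.treatment_deltas(m, design)
        assert np.allclose(deltas["WT"].to_numpy(), 0.0)
        assert warnings == []

    def test_simple_difference(self):
        m, design = self._setup()
        m.loc["s0", "WT_DMSO_r1_cortical_MS2"] = 1.5
        m.loc["s0", "WT_CD_r1_cortical_MS2"] = 0.5
        deltas, _ = hp.treatment_deltas(m, design)
        assert deltas["WT"].loc["s0", "1_cortical_MS2"] == pytest.approx(1.0)

    def test_unpaired_block_skipped_with_warning(self):
        m, design = self._setup(drop=["WT_CD_r2_cortical_MS2"])
        deltas, warnings = hp.treatment_deltas(m, design)
        assert deltas["WT"].shape[1] == 1
        assert deltas["KO"].shape[1] == 2
        assert len(warnings) == 1 and "WT" in warnings[0]

    def test_blocks_pooled_across_region_and_mode(self):
        design = hp.default_tmt_design()  # 2 reps x 2 regions x 2 modes
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(5, len(design.table))),
                         index=[f"s{i}" for i in range(5)],
                         columns=design.table.index)
        deltas, _ = hp.treatment_deltas(m, design)
        assert deltas["WT"].shape[1] == 8  # 2*2*2 blocks per genotype


class TestDifferentialTest:
    def test_identical_groups_null_result(self):
        r = hp.differential_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.diff_z == 0.0 and r.t_stat == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_worked_welch_example(self):
        r = hp.differential_test([2.0, 3.0, 4.0], [0.1, -0.1, 0.05, -0.05])
        t, p = welch_oracle([2.0, 3.0, 4.0], [0.1, -0.1, 0.05, -0.05])
        assert r.diff_z == pytest.approx(3.0, abs=0.01)
        assert r.t_stat == pytest.approx(t)
        assert r.p == pytest.approx(p)

    def test_short_group_untestable(self):
        r = hp.differential_test([1.0], [0.0, 0.1])
        assert not r.testable

    values = st.floats(-5, 5, allow_nan=False).map(lambda x: round(x, 3))

    @given(a=st.lists(values, min_size=2, max_size=10),
           b=st.lists(values, min_size=2, max_size=10))
    @settings(deadline=None, max_examples=400)
    def test_matches_textbook_welch(self, a, b):
        if np.var(a, ddof=1) == 0 or np.var(b, ddof=1) == 0:
            return  # degenerate variances handled separately
        r = hp.differential_test(a, b)
        t, p = welch_oracle(a, b)
        assert r.t_stat == pytest.approx(t, abs=1e-9)
        assert r.p == pytest.approx(p, abs=1e-9)

    @given(a=st.lists(st.floats(-5, 5, allow_nan=False), min_size=2,
                      max_size=8),
           b=st.lists(st.floats(-5, 5, allow_nan=False), min_size=2,
                      max_size=8))
    @settings(deadline=None, max_examples=200)
    def test_antisymmetric_in_group_labels(self, a, b):
        r_ab = hp.differential_test(a, b)
        r_ba = hp.differential_test(b, a)
        assert r_ab.diff_z == pytest.approx(-r_ba.diff_z, abs=1e-12)

    def test_type_one_error_calibration(self):
        """Null sites (both groups standard normal, n=4): the p < 0.05
        fraction stays within 0.05 +/- 0.01."""
        rng = np.random.default_rng(29)
        n_sites = 10_000
        a = rng.normal(size=(n_sites, 4))
        b = rng.normal(size=(n_sites, 4))
        from scipy.stats import ttest_ind
        _, p = ttest_ind(a, b, axis=1, equal_var=False)
        frac = float((p < 0.05).mean())
        assert abs(frac - 0.05) <= 0.01
        # spot-check the vectorised run against the per-site API
        r0 = hp.differential_test(a[0], b[0])
        assert r0.p == pytest.approx(p[0])


class TestCallAndOverlap:
    def _rows(self, ids, p, diff_z):
        return pd.DataFrame({"site_id": ids, "diff_z": diff_z,
                             "t_stat": 1.0, "p": p,
                             "significant": [x < 0.05 for x in p],
                             "testable": True})

    def test_disjoint_sets_empty_overlap(self):
        rows = self._rows(["a", "b"], [0.01, 0.01], [1.0, 1.0])
        hits, overlap, _ = hp.call_and_overlap(rows, 0.05, {"x", "y"})
        assert hits == {"a", "b"} and overlap == set()

    def test_identical_sets_full_overlap(self):
        ids = [f"s{i}" for i in range(7)]
        rows = self._rows(ids, [0.01] * 7, [1.0] * 7)
        hits, overlap, _ = hp.call_and_overlap(rows, 0.05, set(ids))
        assert len(overlap) == 7

    def test_sign_convention_excludes_negative_diff(self):
        rows = self._rows(["a", "b"], [0.01, 0.01], [1.0, -1.0])
        hits, _, _ = hp.call_and_overlap(rows, 0.05, set())
        assert hits == {"a"}

    def test_id_mapping_and_unmapped_count(self):
        rows = self._rows(["n1", "n2"], [0.01, 0.01], [1.0, 1.0])
        hits, overlap, n_unmapped = hp.call_and_overlap(
            rows, 0.05, {"f1", "f2", "f3"}, id_mapping={"f1": "n1"})
        assert overlap == {"n1"} and n_unmapped == 2

    def test_joint_truth_recovery(self, planted_truth):
        """Sites planted in both the SILAC and TMT generators are
        recovered by the joint pipeline: at least 18 of 20 at alpha 0.05."""
        matrix, design, planted = hp.gen_tmt(planted_truth, seed=11)
        normed = hp.zscore_normalize(matrix)
        deltas, _ = hp.treatment_deltas(normed, design)
        rows = hp.differential_table(deltas["WT"], deltas["KO"])
        _, overlap, _ = hp.call_and_overlap(rows, 0.05, planted)
        assert len(overlap) >= 18
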