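"""Welch tests, decision matrices, the four-index rule, robustness battery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sstats

from eegstates.decisions import (
    TABLE_MODALITY_ORDER,
    combine_decisions,
    combined_matrix,
    load_reference_combined,
    load_reference_decision_tables,
    pairwise_decision_matrix,
    robustness_battery,
    welch_t_test,
)


def welch_oracle(x, y):
    """Textbook Welch statistic with Satterthwaite degrees of freedom."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * sstats.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0 and not res.reject

    def test_matches_textbook_oracle(self):
        x, y = [1, 2, 3, 4, 5], [2, 4, 6, 8, 10]
        res = welch_t_test(x, y)
        t, df, p = welch_oracle(x, y)
        assert res.t == pytest.approx(t, abs=1e-9)
        assert res.df == pytest.approx(df, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-9)

    def test_random_pairs_match_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(size=rng.integers(3, 20))
            y = rng.normal(loc=rng.normal(), size=rng.integers(3, 20))
            res = welch_t_test(x, y)
            t, df, p = welch_oracle(x, y)
            assert res.t == pytest.approx(t, abs=1e-9)
            assert res.df == pytest.approx(df, abs=1e-9)
            assert res.p == pytest.approx(p, abs=1e-9)

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_degenerate_zero_variance(self):
        equal = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert equal.p == 1.0 and equal.degenerate and not equal.reject
        unequal = welch_t_test([2.0, 2.0], [3.0, 3.0])
        assert unequal.reject and unequal.degenerate

    @given(shift=st.floats(0.0, 5.0))
    def test_symmetry(self, shift):
        rng = np.random.default_rng(11)
        x = rng.normal(size=10)
        y = rng.normal(loc=shift, size=12)
        a, b = welch_t_test(x, y), welch_t_test(y, x)
        assert a.t == pytest.approx(-b.t, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_p_monotone_in_mean_shift(self, rng):
        x = rng.normal(size=15)
        y0 = rng.normal(size=15)
        y0 -= y0.mean() - x.mean()  # start at equal means
        pvals = [welch_t_test(x, y0 + d).p for d in np.linspace(0, 3, 13)]
        assert all(a >= b - 1e-12 for a, b in zip(pvals, pvals[1:]))


class TestPairwiseMatrix:
    def test_null_calibration(self):
        """Under identical distributions the per-pair type-I error is ~ alpha."""
        rng = np.random.default_rng(314)
        n_rej = n_tests = 0
        for _ in range(200):
            data = {m: rng.normal(size=11) for m in TABLE_MODALITY_ORDER}
            dm = pairwise_decision_matrix(data, index_kind="H", group="Meditator")
            iu = np.triu_indices(6, k=1)
            n_rej += int(dm.decisions[iu].sum())
            n_tests += len(iu[0])
        rate = n_rej / n_tests
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_tests)
        assert abs(rate - 0.05) < half + 0.01  # bound padded for pair dependence

    def test_large_shift_detected(self, rng):
        data = {m: rng.normal(size=11) for m in TABLE_MODALITY_ORDER}
        pooled_sd = np.std(np.concatenate(list(data.values())), ddof=1)
        data["VDO"] = data["VDO"] + 5 * pooled_sd
        dm = pairwise_decision_matrix(data, index_kind="H", group="Meditator")
        assert dm.decision("MED", "VDO") == 1

    def test_matrix_symmetric(self, rng):
        data = {m: rng.normal(size=8) for m in TABLE_MODALITY_ORDER}
        dm = pairwise_decision_matrix(data)
        np.testing.assert_array_equal(dm.decisions, dm.decisions.T)

    def test_missing_modality_listed(self, rng):
        data = {m: rng.normal(size=5) for m in TABLE_MODALITY_ORDER[:-1]}
        with pytest.raises(ValueError, match="VDO"):
            pairwise_decision_matrix(data)

    def test_single_participant_rejected(self, rng):
        data = {m: rng.normal(size=11) for m in TABLE_MODALITY_ORDER}
        data["MED"] = data["MED"][:1]
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_decision_matrix(data)


class TestCombinationRule:
    def test_truth_table_partition(self):
        """16 four-bit vectors -> exactly 5 Reject, 6 Neutral, 5 Accept."""
        outcomes = [
            combine_decisions(bits)
            for bits in itertools.product((0, 1), repeat=4)
        ]
        assert outcomes.count("Reject") == 5
        assert outcomes.count("Neutral") == 6
        assert outcomes.count("Accept") == 5

    @pytest.mark.parametrize(
        "bits,expected",
        [
            ((1, 1, 1, 1), "Reject"),
            ((0, 0, 0, 0), "Accept"),
            ((1, 1, 0, 0), "Neutral"),
            ((1, 1, 1, 0), "Reject"),
            ((1, 0, 0, 0), "Accept"),
        ],
    )
    def test_examples(self, bits, expected):
        assert combine_decisions(bits) == expected

    def test_borderline_accept_can_count_as_reject(self):
        bits, border = (1, 1, 0, 0), (False, False, True, False)
        assert combine_decisions(bits, border) == "Neutral"
        assert combine_decisions(bits, border, borderline_as_reject=True) == "Reject"

    def test_invalid_entries_rejected(self):
        with pytest.raises(ValueError):
            combine_decisions((1, 1, 2, 0))
        with pytest.raises(ValueError):
            combine_decisions((1, 1, 1))


class TestReferenceTables:
    """The bundled decision tables of the reference meditation cohort."""

    def test_plain_rule_reproduces_29_of_30(self):
        tables = load_reference_decision_tables()
        expected = load_reference_combined()
        matches, mismatches = 0, []
        for group, dms in tables.items():
            comb = combined_matrix(dms)
            for _, row in expected[group].iterrows():
                if comb.category(row.mod_a, row.mod_b) == row.category:
                    matches += 1
                else:
                    mismatches.append((group, row.mod_a, row.mod_b))
        assert matches == 29
        # the single internally inconsistent published cell
        assert mismatches == [("Meditator", "MM", "VDO")]

    def test_inconsistent_cell_has_two_rejections_and_borderline(self):
        tables = load_reference_decision_tables()
        comb = combined_matrix(tables["Meditator"])
        i, j = comb.modalities.index("MM"), comb.modalities.index("VDO")
        assert comb.rejection_counts[i, j] == 2
        assert tables["Meditator"]["TP"].borderline[i, j]

    def test_borderline_switch_reproduces_all_30(self):
        tables = load_reference_decision_tables()
        expected = load_reference_combined()
        for group, dms in tables.items():
            comb = combined_matrix(dms, borderline_as_reject=True)
            for _, row in expected[group].iterrows():
                assert comb.category(row.mod_a, row.mod_b) == row.category


class TestCombinedMatrix:
    def _dm(self, fill, group="Meditator", kind="H"):
        from eegstates.decisions import DecisionMatrix

        k = len(TABLE_MODALITY_ORDER)
        dec = np.full((k, k), fill, dtype=int)
        np.fill_diagonal(dec, -1)
        return DecisionMatrix(
            index_kind=kind, group=group, modalities=TABLE_MODALITY_ORDER,
            decisions=dec, pvalues=np.full((k, k), np.nan),
            borderline=np.zeros((k, k), dtype=bool),
        )

    def test_all_zero_matrices_give_accept(self):
        comb = combined_matrix([self._dm(0) for _ in range(4)])
        assert (comb.categories[np.triu_indices(6, 1)] == "Accept").all()

    def test_all_one_matrices_give_reject(self):
        comb = combined_matrix([self._dm(1) for _ in range(4)])
        assert (comb.categories[np.triu_indices(6, 1)] == "Reject").all()

    def test_mismatched_groups_rejected(self):
        dms = [self._dm(0) for _ in range(3)] + [self._dm(0, group="Non-Meditator")]
        with pytest.raises(ValueError, match="mismatched groups"):
            combined_matrix(dms)


class TestRobustnessBattery:
    def _cohort(self, rng, shift=0.0, n=11):
        rows = []
        for m in TABLE_MODALITY_ORDER:
            vals = rng.normal(size=n) + (shift if m == "VDO" else 0.0)
            rows += [
                {"participant": f"p{i}", "modality": m, "value": v}
                for i, v in enumerate(vals)
            ]
        return pd.DataFrame(rows)

    def test_null_cohort_bonferroni_rarely_rejects(self):
        rng = np.random.default_rng(99)
        clean = 0
        for _ in range(100):
            report = robustness_battery(self._cohort(rng))
            rejections = sum(
                cell["reject"] for cell in report["bonferroni_pairwise"].values()
            )
            clean += rejections == 0
        assert clean >= 95

    def test_shifted_modality_flagged_everywhere(self, rng):
        report = robustness_battery(self._cohort(rng, shift=5.0))
        assert report["anova_oneway"]["p"] < 0.001
        assert report["friedman"]["p"] < 0.001
        assert report["anova_rm"]["p"] < 0.001
        vdo_cells = [
            cell
            for pair, cell in report["bonferroni_pairwise"].items()
            if "VDO" in pair
        ]
        assert all(cell["reject"] for cell in vdo_cells)

    def test_normality_tests_pass_on_normal_fixture(self):
        rng = np.random.default_rng(5)
        rows = [
            {"participant": f"p{i}", "modality": m, "value": v}
            for m in ("MED", "VDO")
            for i, v in enumerate(rng.normal(size=500))
        ]
        report = robustness_battery(pd.DataFrame(rows))
        for entry in report["normality"].values():
            assert entry["shapiro_wilk"]["p"] > 0.05
            assert entry["dagostino_k2"]["p"] > 0.05
            assert entry["kolmogorov_smirnov"]["p"] > 0.05
            assert not entry["anderson_darling"]["reject_5pct"]

    def test_unbalanced_design_marks_rm_unavailable(self, rng):
        data = self._cohort(rng)
        data = data[~((data.participant == "p0") & (data.modality == "MED"))]
        report = robustness_battery(data)
        assert "unavailable" in report["anova_rm"]
        assert "unavailable" in report["friedman"]
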