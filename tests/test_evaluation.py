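"""Agreement statistics against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prepscore import datasets
from prepscore.evaluation import (
    DegenerateInputError,
    PairedScores,
    agreement_report,
    bland_altman,
    icc_2_1,
    lin_ccc,
    mae,
    pct_within,
    pearson_r,
    rmse,
    spearman_rho,
)

from _oracles import (
    oracle_bland_altman,
    oracle_ccc,
    oracle_icc_2_1,
    oracle_mae,
    oracle_pearson,
    oracle_rmse,
    oracle_spearman,
)

# ---------------------------------------------------------------------------


def random_pairs(rng, n):
    ref = rng.uniform(0, 20, n)
    pred = np.clip(ref + rng.normal(0, 2, n), 0, 20)
    if np.var(ref) == 0 or np.var(pred) == 0:
        pred = pred + np.arange(n) * 0.01
    return PairedScores(ref, pred)


def test_all_statistics_match_bruteforce_on_random_instances():
    """100 random instances, n <= 20, agreement to 1e-9."""
    rng = np.random.default_rng(202)
    for _ in range(100):
        n = int(rng.integers(3, 21))
        p = random_pairs(rng, n)
        x, y = list(p.reference), list(p.predicted)
        assert mae(p) == pytest.approx(oracle_mae(x, y), abs=1e-9)
        assert rmse(p) == pytest.approx(oracle_rmse(x, y), abs=1e-9)
        assert pearson_r(p) == pytest.approx(oracle_pearson(x, y), abs=1e-9)
        assert spearman_rho(p) == pytest.approx(oracle_spearman(x, y), abs=1e-9)
        ccc, cb = lin_ccc(p)
        assert ccc == pytest.approx(oracle_ccc(x, y), abs=1e-9)
        assert cb == pytest.approx(oracle_ccc(x, y) / oracle_pearson(x, y), abs=1e-9)
        assert bland_altman(p) == pytest.approx(oracle_bland_altman(x, y), abs=1e-9)
        k = int(rng.integers(2, 5))
        m = rng.uniform(0, 20, (n, k))
        assert icc_2_1(m) == pytest.approx(
            oracle_icc_2_1(m.tolist()), abs=1e-9
        )


def test_icc_matches_independent_implementation():
    """Cross-check ICC(2,1) against pingouin's ANOVA-based routine."""
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(7)
    m = rng.uniform(0, 20, (8, 3))
    long = pd.DataFrame(
        {
            "case": np.repeat(np.arange(8), 3),
            "rater": np.tile(np.arange(3), 8),
            "score": m.ravel(),
        }
    )
    icc_table = pingouin.intraclass_corr(
        long, targets="case", raters="rater", ratings="score"
    )
    by_type = icc_table.set_index("Type")["ICC"]
    label = "ICC(A,1)" if "ICC(A,1)" in by_type.index else "ICC2"
    expected = float(by_type.loc[label])
    assert icc_2_1(m) == pytest.approx(expected, abs=1e-9)


class TestClosedForms:
    def test_identical_vectors(self):
        p = PairedScores([3, 7, 12, 18], [3, 7, 12, 18])
        assert mae(p) == 0 and rmse(p) == 0
        ccc, cb = lin_ccc(p)
        assert ccc == pytest.approx(1.0) and cb == pytest.approx(1.0)
        assert bland_altman(p) == pytest.approx((0, 0, 0))
        assert pct_within(p, [0, 1])[0.0] == 100.0

    def test_identical_raters_icc_one(self):
        col = np.array([[1.0], [5.0], [9.0], [14.0]])
        assert icc_2_1(np.hstack([col, col])) == pytest.approx(1.0)

    def test_constant_shift_penalizes_ccc_not_r(self):
        x = np.linspace(0, 18, 30)
        p = PairedScores(x, x + 2.0)
        assert pearson_r(p) == pytest.approx(1.0)
        ccc, cb = lin_ccc(p)
        assert ccc < 1.0
        assert cb == pytest.approx(ccc)  # r = 1 so Cb = ccc

    def test_shifted_rater_icc_below_one(self):
        col = np.linspace(0, 19, 10)[:, None]
        assert icc_2_1(np.hstack([col, col + 1.5])) < 1.0

    def test_perfect_linear_and_reversed(self):
        x = np.arange(1.0, 11)
        assert pearson_r(PairedScores(x, 2 * x + 1)) == pytest.approx(1.0)
        assert spearman_rho(PairedScores(x, 2 * x + 1)) == pytest.approx(1.0)
        assert spearman_rho(PairedScores(x, x[::-1])) == pytest.approx(-1.0)

    def test_two_symmetric_differences(self):
        p = PairedScores([0.0, 0.0], [-1.0, 1.0])
        bias, lo, hi = bland_altman(p)
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * np.sqrt(2))
        assert lo == pytest.approx(-1.96 * np.sqrt(2))

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateInputError):
            pearson_r(PairedScores([1, 1, 1], [1, 2, 3]))
        with pytest.raises(DegenerateInputError):
            lin_ccc(PairedScores([1, 2, 3], [5, 5, 5]))
        with pytest.raises(DegenerateInputError):
            icc_2_1(np.full((4, 2), 3.0))


class TestPctWithin:
    def test_threshold_semantics_and_monotonicity(self):
        p = PairedScores([10, 10, 10, 10], [10, 11, 12, 13.5])
        out = pct_within(p, [0, 1, 2, 3, 4])
        assert out == {0.0: 25.0, 1.0: 50.0, 2.0: 75.0, 3.0: 75.0, 4.0: 100.0}
        vals = list(out.values())
        assert vals == sorted(vals)

    def test_boundary_is_inclusive(self):
        p = PairedScores([0.0, 0.0], [1.0, 3.0])
        assert pct_within(p, [1.0])[1.0] == 50.0


class TestInvarianceProperties:
    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-3, 3))
    def test_constant_offset_shifts_bias_only(self, seed, c):
        rng = np.random.default_rng(seed)
        p = random_pairs(rng, 12)
        q = PairedScores(p.reference, p.predicted + c)
        assert bland_altman(q)[0] == pytest.approx(bland_altman(p)[0] + c, abs=1e-9)
        assert pearson_r(q) == pytest.approx(pearson_r(p), abs=1e-9)
        if c != 0:
            base = abs(p.reference.mean() - p.predicted.mean())
            shifted = abs(p.reference.mean() - q.predicted.mean())
            if shifted > base:  # moved further from the identity line
                assert lin_ccc(q)[0] <= lin_ccc(p)[0] + 1e-12

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_report_internal_consistency(self, seed):
        rng = np.random.default_rng(seed)
        p = random_pairs(rng, 15)
        rep = agreement_report(p, thresholds=(0.5, 1, 2))
        assert rep.rmse >= rep.mae >= 0
        assert rep.loa_low <= rep.bias <= rep.loa_high
        assert abs(rep.pearson_r) <= 1 + 1e-12
        assert rep.ccc <= abs(rep.pearson_r) + 1e-12  # Cb <= 1
        vals = [rep.pct_within[t] for t in (0.5, 1.0, 2.0)]
        assert vals == sorted(vals)


class TestReferenceTables:
    """Statistics recomputed from the feasibility study's printed tables."""

    def test_test_split_derived_statistics(self):
        true, pred = datasets.reference_totals("test")
        p = PairedScores(true, pred)
        assert mae(p) == pytest.approx(0.95, abs=1e-3)
        assert rmse(p) == pytest.approx(1.1406, abs=1e-3)
        assert pearson_r(p) == pytest.approx(0.9412, abs=1e-3)
        assert bland_altman(p)[0] == pytest.approx(0.23, abs=1e-3)
        # the printed rounded pairs happen to reproduce the reported ccc
        assert lin_ccc(p)[0] == pytest.approx(0.839, abs=1e-3)

    def test_train_split_within_threshold_recomputation(self):
        true, pred = datasets.reference_totals("train")
        out = pct_within(PairedScores(true, pred), [1.0, 2.0])
        assert out[1.0] == pytest.approx(75.0)
        assert out[2.0] == pytest.approx(100.0)

    def test_tables_are_complete(self):
        assert len(datasets.load_reference_table("train")) == 20
        assert len(datasets.load_reference_table("test")) == 10


def test_agreement_plots_written(tmp_path):
    from prepscore import datasets
    from prepscore.plots import bland_altman_plot, scatter_plot

    true, pred = datasets.reference_totals("test")
    p = PairedScores(true, pred)
    s = scatter_plot(p, tmp_path / "scatter.svg", title="test split")
    b = bland_altman_plot(p, tmp_path / "ba.png")
    assert s.stat().st_size > 0
    assert b.stat().st_size > 0
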