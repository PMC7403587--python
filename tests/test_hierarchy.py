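"""OLS fits, adjusted R^2 accounting, and hierarchical regression ledgers."""

import numpy as np
import pandas as pd
import pytest

from shiftwork.exceptions import (
    CollinearityError,
    InsufficientDataError,
)
from shiftwork.hierarchy import (
    PredictorBlock,
    adjusted_r2,
    fit_ols,
    hierarchical_ledger,
)


def ols_oracle(y, X):
    """Independent least-squares summary via raw normal equations."""
    n = len(y)
    D = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - sse / sst
    p = X.shape[1]
    f = (r2 / p) / ((1 - r2) / (n - p - 1))
    return r2, f


class TestFitOLS:
    def test_exact_linear_relationship(self):
        x = np.arange(10.0)
        fit = fit_ols(3 * x + 1, x)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_orthogonal_outcome(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0, -1.0, 1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        y = y - y.mean()
        y = y - x * (x @ y) / (x @ x)  # project out x exactly
        fit = fit_ols(y, x)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)
        assert fit.f == pytest.approx(0.0, abs=1e-12)

    def test_three_point_hand_fixture(self):
        fit = fit_ols(np.array([1.0, 2.0, 4.0]), np.array([0.0, 1.0, 2.0]))
        assert fit.r2 == pytest.approx(27 / 28)

    def test_matches_normal_equation_oracle(self, rng):
        for _ in range(20):
            n, p = 25, 3
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) + rng.normal(size=n)
            fit = fit_ols(y, X)
            r2, f = ols_oracle(y, X)
            assert fit.r2 == pytest.approx(r2, abs=1e-10)
            assert fit.f == pytest.approx(f, rel=1e-8)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=10)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(CollinearityError) as err:
            fit_ols(rng.normal(size=10), X, names=["a", "b"])
        assert "b" in err.value.columns

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_ols(np.arange(4.0), np.arange(12.0).reshape(4, 3))


class TestAdjustedR2:
    def test_perfect_fit_stays_one(self):
        assert adjusted_r2(1.0, 10, 3) == pytest.approx(1.0)

    def test_closed_form_value(self):
        assert adjusted_r2(0.5, 13, 2) == pytest.approx(0.4)

    def test_can_be_negative(self):
        assert adjusted_r2(0.20, 10, 6) == pytest.approx(-1.4)

    def test_requires_spare_degrees_of_freedom(self):
        with pytest.raises(InsufficientDataError):
            adjusted_r2(0.5, 4, 3)

    def test_identity_against_residual_computation(self, rng):
        n, p = 30, 4
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        fit = fit_ols(y, X)
        # direct: 1 - (SSE/(n-p-1)) / (SST/(n-1))
        D = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        sse = float(((y - D @ beta) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        direct = 1 - (sse / (n - p - 1)) / (sst / (n - 1))
        assert fit.adj_r2 == pytest.approx(direct, abs=1e-10)


def _blocks():
    return [
        PredictorBlock("one", ("x1",)),
        PredictorBlock("two", ("x2", "x3")),
    ]


class TestHierarchicalLedger:
    def _data(self, rng, n=40, betas=(1.0, 0.5, 0.0), noise=1.0):
        X = rng.normal(size=(n, 3))
        y = X @ np.asarray(betas) + rng.normal(0, noise, n)
        return pd.DataFrame(
            {"y": y, "x1": X[:, 0], "x2": X[:, 1], "x3": X[:, 2]}
        )

    def test_r2_nondecreasing_across_steps(self, rng):
        for _ in range(10):
            ledger = hierarchical_ledger(self._data(rng), "y", _blocks())
            r2s = [s.r2 for s in ledger.steps]
            assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_step_accounting(self, rng):
        ledger = hierarchical_ledger(self._data(rng), "y", _blocks())
        assert [s.cumulative_predictors for s in ledger.steps] == [1, 3]
        assert ledger.steps[0].delta_adj_r2 is None
        assert ledger.steps[1].delta_adj_r2 == pytest.approx(
            ledger.steps[1].adj_r2 - ledger.steps[0].adj_r2
        )
        assert ledger.steps[1].df1 == 3
        assert ledger.steps[1].df2 == ledger.n - 4

    def test_listwise_deletion_reported_in_n(self, rng):
        data = self._data(rng, n=20)
        data.loc[3, "x2"] = np.nan
        data.loc[7, "y"] = np.nan
        ledger = hierarchical_ledger(data, "y", _blocks())
        assert ledger.n == 18

    def test_duplicate_variable_across_blocks_rejected(self, rng):
        blocks = [PredictorBlock("one", ("x1",)), PredictorBlock("two", ("x1", "x2"))]
        with pytest.raises(CollinearityError):
            hierarchical_ledger(self._data(rng), "y", blocks)

    def test_partial_f_available_behind_flag(self, rng):
        ledger = hierarchical_ledger(self._data(rng), "y", _blocks(), partial_f=True)
        assert ledger.steps[0].partial_f is None
        assert ledger.steps[1].partial_f is not None
        assert ledger.steps[1].partial_p <= 1.0

    def test_small_sample_warning(self, rng):
        data = self._data(rng, n=8)
        with pytest.warns(UserWarning):
            hierarchical_ledger(data, "y", _blocks())

    def test_informative_block_raises_adjusted_r2(self):
        """A second block holding the true covariate (standardized effect
        0.8, n = 13) yields a positive adjusted-R^2 change in >= 90% of
        replicate data sets."""
        rng = np.random.default_rng(17)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            n = 13
            x1 = rng.normal(size=n)
            x2 = rng.normal(size=n)
            y = 0.8 * x2 + rng.normal(size=n)
            data = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
            ledger = hierarchical_ledger(
                data, "y", [PredictorBlock("noise", ("x1",)), PredictorBlock("signal", ("x2",))]
            )
            if ledger.steps[1].delta_adj_r2 > 0:
                hits += 1
        assert hits / n_rep >= 0.90

    def test_null_block_does_not_raise_adjusted_r2_on_average(self):
        rng = np.random.default_rng(23)
        deltas = []
        for _ in range(200):
            n = 40
            x1 = rng.normal(size=n)
            x2 = rng.normal(size=n)
            y = x1 + rng.normal(size=n)
            data = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
            ledger = hierarchical_ledger(
                data, "y", [PredictorBlock("signal", ("x1",)), PredictorBlock("noise", ("x2",))]
            )
            deltas.append(ledger.steps[1].delta_adj_r2)
        assert np.mean(deltas) < 0.01

    def test_to_frame_layout(self, rng):
        frame = hierarchical_ledger(self._data(rng), "y", _blocks()).to_frame()
        assert list(frame["step"]) == [1, 2]
        assert set(frame.columns) >= {"outcome", "block", "R2", "adjR2", "deltaAdjR2", "F", "p"}
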