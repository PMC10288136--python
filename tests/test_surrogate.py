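"""RBF surrogate: interpolation exactness, smooth-function recovery,
invariances and the holdout validation scores."""

import numpy as np
import pandas as pd
import pytest

from cabtherm import ConfigurationError, cross_validate, fit_rbf, opt_lhd
from cabtherm.doe import DesignMatrix

RANGES = {"x1": (0.0, 1.0), "x2": (-2.0, 2.0), "x3": (10.0, 20.0)}


@pytest.fixture(scope="module")
def design():
    return opt_lhd(40, RANGES, seed=7, budget=2000)


def _quadratic(frame: pd.DataFrame) -> np.ndarray:
    # smooth test response: sum of squares in normalised coordinates
    z = [(frame[k] - lo) / (hi - lo) for k, (lo, hi) in RANGES.items()]
    return sum(v**2 for v in z).to_numpy()


class TestFitPredict:
    def test_interpolates_training_points(self, design):
        y = _quadratic(design.frame)
        model = fit_rbf(design, y)
        yhat = model.predict_rows(design.frame)
        assert np.allclose(yhat, y, rtol=1e-8, atol=1e-10)

    def test_constant_response_reproduced_everywhere(self, design):
        model = fit_rbf(design, np.full(design.n, 3.25))
        probe = pd.DataFrame({"x1": [0.31, 0.77], "x2": [-1.2, 0.4],
                              "x3": [12.0, 19.0]})
        assert np.allclose(model.predict_rows(probe), 3.25, atol=1e-8)

    def test_row_order_invariance(self, design):
        y = _quadratic(design.frame)
        perm = np.random.default_rng(0).permutation(design.n)
        shuffled = DesignMatrix(
            frame=design.frame.iloc[perm].reset_index(drop=True),
            ranges=design.ranges, categorical=design.categorical, seed=design.seed)
        a = fit_rbf(design, y)
        b = fit_rbf(shuffled, y[perm])
        probe = pd.DataFrame({"x1": [0.5], "x2": [0.0], "x3": [15.0]})
        assert a.predict_rows(probe)[0] == pytest.approx(b.predict_rows(probe)[0],
                                                         abs=1e-9)

    def test_symmetric_data_symmetric_prediction(self):
        # f(x) = x^2 on [-1, 1]: midpoint predictions at +/-z must agree
        frame = pd.DataFrame({"x": np.linspace(-1, 1, 9)})
        d = DesignMatrix(frame=frame, ranges={"x": (-1.0, 1.0)})
        model = fit_rbf(d, frame["x"].to_numpy() ** 2)
        probe = pd.DataFrame({"x": [-0.35, 0.35]})
        lo, hi = model.predict_rows(probe)
        assert lo == pytest.approx(hi, abs=1e-9)

    def test_extrapolation_warns(self, design):
        model = fit_rbf(design, _quadratic(design.frame))
        probe = pd.DataFrame({"x1": [1.5], "x2": [0.0], "x3": [15.0]})
        with pytest.warns(UserWarning, match="extrapolat"):
            model.predict_rows(probe)

    def test_duplicate_rows_rejected(self, design):
        frame = pd.concat([design.frame, design.frame.iloc[[0]]],
                          ignore_index=True)
        dup = DesignMatrix(frame=frame, ranges=design.ranges,
                           categorical=design.categorical)
        with pytest.raises(ConfigurationError, match="duplicate"):
            fit_rbf(dup, np.zeros(len(frame)))

    def test_too_few_rows_rejected(self):
        frame = pd.DataFrame({"x1": [0.1, 0.5], "x2": [0.0, 1.0],
                              "x3": [11.0, 19.0]})
        d = DesignMatrix(frame=frame, ranges=RANGES)
        with pytest.raises(ConfigurationError, match="rows"):
            fit_rbf(d, np.zeros(2))


class TestCrossValidate:
    def test_smooth_function_recovery(self):
        d = opt_lhd(50, RANGES, seed=13, budget=2000)
        responses = pd.DataFrame({"f": _quadratic(d.frame)})
        report = cross_validate(d, responses, fraction=0.2, seed=5)
        assert report.score("f", "r2") >= 0.99

    def test_perfect_surrogate_scores_r2_one(self, design):
        # response generated by an RBF whose centres are exactly the
        # training rows of the validation split: the refit reproduces
        # the same interpolant, so the holdout is predicted exactly
        from cabtherm import split_holdout

        train, _ = split_holdout(design, 0.15, seed=1)
        sub = DesignMatrix(
            frame=design.frame.iloc[train].reset_index(drop=True),
            ranges=design.ranges, categorical=design.categorical)
        generator = fit_rbf(sub, _quadratic(sub.frame))
        responses = pd.DataFrame({"self": generator.predict_rows(design.frame)})
        report = cross_validate(design, responses, fraction=0.15, seed=1)
        assert report.score("self", "r2") == pytest.approx(1.0, abs=1e-6)
        assert report.score("self", "rms") == pytest.approx(0.0, abs=1e-6)

    def test_zero_variance_holdout_reported_undefined(self, design):
        responses = pd.DataFrame({"const": np.full(design.n, 2.0)})
        report = cross_validate(design, responses, fraction=0.15, seed=1)
        assert np.isnan(report.score("const", "r2"))
        assert report.score("const", "rms") == pytest.approx(0.0, abs=1e-8)

    def test_refit_with_holdout_interpolates_it(self, design):
        y = _quadratic(design.frame)
        report = cross_validate(design, pd.DataFrame({"f": y}), 0.15, seed=2)
        model = fit_rbf(design, y)  # all rows, holdout included
        rows = design.frame.iloc[report.holdout_rows]
        assert np.allclose(model.predict_rows(rows), y[report.holdout_rows],
                           rtol=1e-8, atol=1e-10)
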