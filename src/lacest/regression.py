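"""Least-squares fitting, prediction, error statistics, LOOCV, Bland-Altman.

The lactate model Y = A.X is linear in the Taylor-expanded design matrix,
so the coefficient vector A is the ordinary least-squares minimizer of
D = sum ||y_i - A x_i||^2. The normal-equations form (X'X)^{-1} X'Y assumes
full rank; here the system is solved by an SVD-based factorization that
returns the identical answer on full-rank input and the minimum-norm
solution otherwise, with the effective rank recorded and a warning
emitted. Rank deficiency is routine rather than exceptional: a binary sex
variable makes its quadratic and cubic columns exactly collinear with its
linear one.

Error statistics follow the sample convention: residual d = Y - Yhat, sum
of squares D, variance sigma^2 = D/(n-1). Bland-Altman differences are
oriented estimated - measured, with limits of agreement at
bias +/- 1.96 SD of the differences.

Predictions are not clamped here: the polynomial is unbounded and a
negative estimate is information about extrapolation. Clamping at zero is
offered only at the CLI/report layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import Dataset, Intensity
from .errors import (FitError, FoldError, SpecError, StratificationError,
                     ValidationError)
from .features import (DesignMatrix, FeatureSpec, StandardizationParams,
                       build_design_matrix, feature_frame, fit_standardizer)

__all__ = [
    "RankDeficiencyWarning",
    "FittedModel",
    "ErrorStats",
    "BlandAltman",
    "LoocvResult",
    "ValidationReport",
    "fit_least_squares",
    "predict",
    "error_stats",
    "loocv",
    "bland_altman",
    "fit_stratified",
    "STRATA_PAPER",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

#: two-model stratification: low+moderate pooled, high separate
STRATA_PAPER = {
    "low_moderate": (Intensity.LC, Intensity.MC),
    "high": (Intensity.HC,),
}


class RankDeficiencyWarning(UserWarning):
    """The design matrix is rank deficient; the minimum-norm solution is
    returned instead of the unique normal-equations solution."""


@dataclass
class FittedModel:
    """Coefficient vector A for one stratum plus everything needed to
    rebuild the design matrix at prediction time."""

    coefficients: np.ndarray
    columns: list[tuple[str, int]]
    feature_spec: FeatureSpec
    standardization_params: StandardizationParams | None
    stratum: str
    n_train: int
    rank: int

    @property
    def rank_deficient(self) -> bool:
        return self.rank < len(self.coefficients)

    def coefficient(self, variable: str, order: int) -> float:
        """Coefficient of one labelled column (monomial basis)."""
        try:
            idx = self.columns.index((variable, order))
        except ValueError:
            raise SpecError(f"model has no column ({variable!r}, {order})")
        return float(self.coefficients[idx])

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "coefficients": [float(c) for c in self.coefficients],
            "columns": [[v, int(k)] for v, k in self.columns],
            "feature_spec": self.feature_spec.to_dict(),
            "standardization_params": (
                None if self.standardization_params is None
                else self.standardization_params.to_dict()),
            "stratum": self.stratum,
            "n_train": int(self.n_train),
            "rank": int(self.rank),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise SpecError(
                f"unsupported model format version {d.get('format_version')}")
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            columns=[(v, int(k)) for v, k in d["columns"]],
            feature_spec=FeatureSpec.from_dict(d["feature_spec"]),
            standardization_params=(
                None if d["standardization_params"] is None
                else StandardizationParams.from_dict(
                    d["standardization_params"])),
            stratum=d["stratum"],
            n_train=int(d["n_train"]),
            rank=int(d["rank"]),
        )


def save_model(model: FittedModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path) -> FittedModel:
    with open(path, encoding="utf-8") as fh:
        return FittedModel.from_dict(json.load(fh))


def _lstsq(X: np.ndarray, y: np.ndarray, warn: bool = True
           ) -> tuple[np.ndarray, int]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if warn and rank < X.shape[1]:
        warnings.warn(
            f"design matrix is rank deficient (rank {rank} < "
            f"{X.shape[1]} columns); returning the minimum-norm solution",
            RankDeficiencyWarning, stacklevel=3)
    return coef, int(rank)


def fit_least_squares(X: DesignMatrix | np.ndarray, y,
                      spec: FeatureSpec | None = None,
                      params: StandardizationParams | None = None,
                      stratum: str = "combined") -> FittedModel:
    """Solve min_A sum (y_i - A.x_i)^2.

    Accepts a labelled :class:`DesignMatrix` (spec/params taken from it) or
    a plain array (spec/params passed explicitly or left None).
    """
    if isinstance(X, DesignMatrix):
        values, columns = X.values, list(X.columns)
        spec = X.spec if spec is None else spec
        params = X.params if params is None else params
    else:
        values = np.asarray(X, dtype=float)
        columns = [("x", k) for k in range(values.shape[1])]
    y = np.asarray(y, dtype=float)
    if values.size == 0 or y.size == 0:
        raise FitError("cannot fit on empty input")
    if values.shape[0] != y.shape[0]:
        raise FitError(f"X has {values.shape[0]} rows but y has {y.shape[0]}")
    if y.shape[0] < 2:
        raise FitError(f"need >= 2 observations (got {y.shape[0]})")
    if not np.all(np.isfinite(values)) or not np.all(np.isfinite(y)):
        raise ValidationError("non-finite values in regression input")
    coef, rank = _lstsq(values, y)
    return FittedModel(coefficients=coef, columns=columns,
                       feature_spec=spec, standardization_params=params,
                       stratum=stratum, n_train=int(y.shape[0]), rank=rank)


def predict(model: FittedModel, ds: Dataset | np.ndarray) -> np.ndarray:
    """Estimated lactate Yhat = A.X using the model's frozen preprocessing.

    ``ds`` is a Dataset (or raw feature frame); the design matrix is
    rebuilt with the training standardization parameters. No clamping.
    """
    if model.feature_spec is None:
        raise SpecError("model carries no feature spec; cannot rebuild the "
                        "design matrix from records")
    X = build_design_matrix(ds, model.feature_spec,
                            model.standardization_params)
    if len(X.columns) != len(model.coefficients):
        raise SpecError(
            f"design matrix has {len(X.columns)} columns but model has "
            f"{len(model.coefficients)} coefficients")
    return X.values @ model.coefficients


@dataclass
class ErrorStats:
    """Residual summary: d = Y - Yhat, D = sum d^2, sigma^2 = D/(n-1)."""

    residuals: np.ndarray
    sum_squares: float
    variance: float
    sd: float
    bias: float
    percent_errors: np.ndarray

    @property
    def n(self) -> int:
        return int(self.residuals.shape[0])


def error_stats(y_measured, y_estimated) -> ErrorStats:
    """Fitting-error statistics between measured and estimated lactate.

    Percent errors are d_i / y_i, so every measured value must be > 0.
    """
    y = np.asarray(y_measured, dtype=float)
    yhat = np.asarray(y_estimated, dtype=float)
    if y.shape != yhat.shape:
        raise ValidationError(
            f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.shape[0] < 2:
        raise FitError(f"need n >= 2 for a variance (got {y.shape[0]})")
    if np.any(y <= 0):
        raise ValidationError(
            "percent errors require measured values > 0")
    d = y - yhat
    D = float(np.sum(d ** 2))
    var = D / (y.shape[0] - 1)
    return ErrorStats(residuals=d, sum_squares=D, variance=var,
                      sd=float(np.sqrt(var)), bias=float(d.mean()),
                      percent_errors=d / y)


@dataclass
class BlandAltman:
    """Agreement summary; differences oriented estimated - measured.

    Limits of agreement are bias +/- 1.96 SD of the differences (the 95%
    band for Gaussian differences). The percent variant divides each
    difference by the measured value.
    """

    differences: np.ndarray
    bias: float
    sd_diff: float
    lower_loa: float
    upper_loa: float
    percent_differences: np.ndarray
    percent_bias: float
    percent_sd: float
    percent_lower_loa: float
    percent_upper_loa: float

    @property
    def n(self) -> int:
        return int(self.differences.shape[0])


def bland_altman(y_measured, y_estimated) -> BlandAltman:
    y = np.asarray(y_measured, dtype=float)
    yhat = np.asarray(y_estimated, dtype=float)
    if y.shape != yhat.shape:
        raise ValidationError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.shape[0] < 2:
        raise FitError(f"need n >= 2 for limits of agreement (got {y.shape[0]})")
    if np.any(y <= 0):
        raise ValidationError("percent differences require measured values > 0")
    d = yhat - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    pct = d / y
    pbias = float(pct.mean())
    psd = float(pct.std(ddof=1))
    return BlandAltman(
        differences=d, bias=bias, sd_diff=sd,
        lower_loa=bias - 1.96 * sd, upper_loa=bias + 1.96 * sd,
        percent_differences=pct, percent_bias=pbias, percent_sd=psd,
        percent_lower_loa=pbias - 1.96 * psd,
        percent_upper_loa=pbias + 1.96 * psd)


@dataclass
class LoocvResult:
    predictions: np.ndarray
    mse: float

    @property
    def rmse(self) -> float:
        return float(np.sqrt(self.mse))


def loocv(ds: Dataset, spec: FeatureSpec) -> LoocvResult:
    """Leave-one-out cross-validation of the full fitting pipeline.

    For each test record i the standardizer *and* the coefficients are
    refitted on the remaining n-1 records (no preprocessing leakage), then
    record i is predicted. The reported MSE is the mean squared error of
    these held-out predictions, on the lactate (mmol/L) scale.
    """
    frame = feature_frame(ds, spec.variables)
    y = np.asarray(ds.lactate_vector(), dtype=float)
    n = len(frame)
    p = spec.n_columns
    # standardizing inside a fold needs >= 2 training rows
    min_n = 3 if (spec.standardize and spec.variables) else 2
    if n < min_n:
        raise FoldError(f"need >= {min_n} observations for LOOCV (got {n})")
    if n - 1 < p:
        warnings.warn(
            f"LOOCV folds have {n - 1} rows for {p} columns; every fold is "
            "rank deficient and uses the minimum-norm solution",
            RankDeficiencyWarning, stacklevel=2)
    preds = np.empty(n)
    raw = frame.to_numpy(dtype=float)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        train = frame.iloc[mask.nonzero()[0]]
        if spec.standardize:
            params = fit_standardizer(train, spec)
        else:
            params = None
        Xtr = build_design_matrix(train, spec, params)
        coef, _ = _lstsq(Xtr.values, y[mask], warn=False)
        Xte = build_design_matrix(frame.iloc[[i]], spec, params)
        preds[i] = float((Xte.values @ coef)[0])
        mask[i] = True
    mse = float(np.mean((y - preds) ** 2))
    return LoocvResult(predictions=preds, mse=mse)


@dataclass
class ValidationReport:
    """Everything Fig.-1-style validation needs for one stratum."""

    in_sample: ErrorStats
    bland_altman: BlandAltman
    loocv: LoocvResult | None
    measured: np.ndarray
    estimated: np.ndarray

    def summary(self) -> dict:
        out = {
            "n": self.in_sample.n,
            "residual_sd_mmol_l": self.in_sample.sd,
            "residual_variance": self.in_sample.variance,
            "bias_mmol_l": self.bland_altman.bias,
            "sd_diff_mmol_l": self.bland_altman.sd_diff,
            "lower_loa_mmol_l": self.bland_altman.lower_loa,
            "upper_loa_mmol_l": self.bland_altman.upper_loa,
            "percent_bias": self.bland_altman.percent_bias,
            "percent_sd": self.bland_altman.percent_sd,
            "percent_lower_loa": self.bland_altman.percent_lower_loa,
            "percent_upper_loa": self.bland_altman.percent_upper_loa,
        }
        if self.loocv is not None:
            out["loocv_mse"] = self.loocv.mse
            out["loocv_rmse"] = self.loocv.rmse
        return out

    def to_frame(self):
        """Per-observation table (measured, estimated, differences)."""
        import pandas as pd

        data = {
            "measured_mmol_l": self.measured,
            "estimated_mmol_l": self.estimated,
            "difference_mmol_l": self.bland_altman.differences,
            "percent_difference": self.bland_altman.percent_differences,
        }
        if self.loocv is not None:
            data["loocv_estimate_mmol_l"] = self.loocv.predictions
        return pd.DataFrame(data)


def _strata_indices(ds: Dataset, strategy: str) -> dict[str, list[int]]:
    if strategy == "paper":
        groups = {name: [i for i, t in enumerate(ds.tests)
                         if t.intensity in members]
                  for name, members in STRATA_PAPER.items()}
    elif strategy == "combined":
        groups = {"combined": list(range(len(ds.tests)))}
    else:
        raise SpecError(f"unknown strategy {strategy!r}; "
                        "expected 'paper' or 'combined'")
    for name, idx in groups.items():
        if not idx:
            raise StratificationError(f"stratum {name!r} is empty")
    return groups


def fit_stratified(ds: Dataset, spec: FeatureSpec, strategy: str = "paper",
                   run_loocv: bool = True
                   ) -> dict[str, tuple[FittedModel, ValidationReport]]:
    """Fit and validate one model per intensity stratum.

    ``strategy='paper'`` pools low and moderate tests in one model and fits
    high-intensity tests separately (the configuration found to fit well);
    ``strategy='combined'`` fits a single model on all tests. Each stratum
    gets its own standardizer, in-sample error statistics, Bland-Altman
    agreement and (optionally) LOOCV.
    """
    out: dict[str, tuple[FittedModel, ValidationReport]] = {}
    for name, idx in _strata_indices(ds, strategy).items():
        sub = ds.subset_tests(idx)
        y = np.asarray(sub.lactate_vector(), dtype=float)
        params = fit_standardizer(sub, spec) if spec.standardize else None
        X = build_design_matrix(sub, spec, params)
        model = fit_least_squares(X, y, stratum=name)
        yhat = X.values @ model.coefficients
        report = ValidationReport(
            in_sample=error_stats(y, yhat),
            bland_altman=bland_altman(y, yhat),
            loocv=loocv(sub, spec) if run_loocv else None,
            measured=y, estimated=yhat)
        out[name] = (model, report)
    return out
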