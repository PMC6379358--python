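"""Design-matrix construction: standardization and polynomial expansion.

The lactate model is an exponential function of the physiologic and
anthropometric variables, linearized by a cubic Taylor expansion about the
cohort mean. After z-scoring each variable, the expansion point is 0 and
the polynomial basis for a variable is simply (z, z^2, ..., z^degree); an
intercept column is prepended. The Taylor signs and factorial divisors are
absorbed into the fitted coefficients: least squares is invariant to any
fixed invertible per-column rescaling, so plain monomials are used as the
canonical basis (coefficient mapping: a0 = c0, -a1 = c1, a2/2! = c2,
-a3/3! = c3 for the signed/factorial convention).

Variables on wildly different scales (age in years vs tidal volume in
liters) make unscaled cubics ill-conditioned, so standardization defaults
to on; the training-set parameters are frozen into the fitted model and
reused at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import Dataset, Sex
from .errors import DegenerateFeatureError, SpecError, ValidationError

__all__ = [
    "VARIABLES",
    "DEFAULT_VARIABLES",
    "encode_sex",
    "FeatureSpec",
    "StandardizationParams",
    "DesignMatrix",
    "feature_frame",
    "fit_standardizer",
    "build_design_matrix",
]

#: the documented variable vocabulary, in canonical order
VARIABLES = ("vt", "bf", "resting_hr", "ex_hr", "age", "bmi", "sex")
DEFAULT_VARIABLES = VARIABLES

_INTERCEPT = ("intercept", 0)


def encode_sex(sex) -> int:
    """Fixed numeric coding used at feature time: male -> 1, female -> 0."""
    if isinstance(sex, Sex):
        sex = sex.value
    if sex == "male":
        return 1
    if sex == "female":
        return 0
    raise ValidationError(f"cannot encode sex {sex!r}: expected male/female")


@dataclass(frozen=True)
class FeatureSpec:
    """Which variables enter the model and how they are expanded.

    ``variables`` may be empty, which yields an intercept-only design.
    ``degree`` is the order of the polynomial expansion (3 reproduces the
    cubic Taylor approximation of the exponential link).
    """

    variables: tuple[str, ...] = DEFAULT_VARIABLES
    degree: int = 3
    standardize: bool = True

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        if self.degree < 1:
            raise SpecError(f"degree must be >= 1 (got {self.degree})")
        unknown = [v for v in self.variables if v not in VARIABLES]
        if unknown:
            raise SpecError(f"unknown variable(s) {unknown}; "
                            f"vocabulary is {list(VARIABLES)}")
        if len(set(self.variables)) != len(self.variables):
            raise SpecError(f"duplicate variables in {list(self.variables)}")

    @property
    def n_columns(self) -> int:
        return 1 + self.degree * len(self.variables)

    def to_dict(self) -> dict:
        return {"variables": list(self.variables), "degree": self.degree,
                "standardize": self.standardize}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(variables=tuple(d.get("variables", DEFAULT_VARIABLES)),
                   degree=int(d.get("degree", 3)),
                   standardize=bool(d.get("standardize", True)))


@dataclass(frozen=True)
class StandardizationParams:
    """Per-variable training means and sample SDs (denominator n-1)."""

    means: dict[str, float]
    sds: dict[str, float]

    def covers(self, variables) -> bool:
        return all(v in self.means and v in self.sds for v in variables)

    def to_dict(self) -> dict:
        return {"means": dict(self.means), "sds": dict(self.sds)}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(means={k: float(v) for k, v in d["means"].items()},
                   sds={k: float(v) for k, v in d["sds"].items()})


@dataclass
class DesignMatrix:
    """n x (1 + degree*p) matrix with labelled columns.

    Column 0 is the intercept; the remaining labels are (variable, order)
    pairs grouped by variable. Row order matches the source test records.
    """

    values: np.ndarray
    columns: list[tuple[str, int]]
    spec: FeatureSpec
    params: StandardizationParams | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]


def feature_frame(ds: Dataset, variables=DEFAULT_VARIABLES) -> pd.DataFrame:
    """Raw (unstandardized) feature values, one row per test record."""
    unknown = [v for v in variables if v not in VARIABLES]
    if unknown:
        raise SpecError(f"unknown variable(s) {unknown}")
    smap = ds.subject_map
    rows = []
    for i, t in enumerate(ds.tests):
        if t.subject_id not in smap:
            raise ValidationError(
                f"tests row {i}: subject_id {t.subject_id!r} unresolved")
        s = smap[t.subject_id]
        row = {
            "vt": t.vt_l,
            "bf": t.bf,
            "resting_hr": s.resting_hr,
            "ex_hr": t.ex_hr,
            "age": s.age,
            "bmi": s.bmi,
            "sex": float(encode_sex(s.sex)),
        }
        rows.append([row[v] for v in variables])
    return pd.DataFrame(rows, columns=list(variables), dtype=float)


def fit_standardizer(data, spec: FeatureSpec) -> StandardizationParams:
    """Estimate per-variable mean and sample SD on training data.

    ``data`` is a Dataset or a raw feature frame. Raises
    :class:`DegenerateFeatureError` if a variable is constant.
    """
    frame = data if isinstance(data, pd.DataFrame) else \
        feature_frame(data, spec.variables)
    if len(frame) < 2:
        raise DegenerateFeatureError(
            f"need >= 2 rows to standardize (got {len(frame)})")
    means, sds = {}, {}
    for v in spec.variables:
        col = frame[v].to_numpy(dtype=float)
        m = float(col.mean())
        s = float(col.std(ddof=1))
        if s <= 0.0:
            raise DegenerateFeatureError(
                f"variable {v!r} is constant on the training data "
                "(SD = 0); it cannot be standardized")
        means[v], sds[v] = m, s
    return StandardizationParams(means=means, sds=sds)


def _expand(z: np.ndarray, degree: int) -> np.ndarray:
    """Monomials z, z^2, ..., z^degree as columns."""
    return np.column_stack([z ** k for k in range(1, degree + 1)])


def build_design_matrix(ds, spec: FeatureSpec,
                        params: StandardizationParams | None = None
                        ) -> DesignMatrix:
    """Standardize and polynomially expand the features of ``ds``.

    ``ds`` may be a Dataset or a raw feature frame. When
    ``spec.standardize`` is set, ``params`` must cover every variable;
    otherwise raw values are expanded directly (used by test oracles that
    need fixed preprocessing).
    """
    frame = ds if isinstance(ds, pd.DataFrame) else \
        feature_frame(ds, spec.variables)
    n = len(frame)
    if spec.standardize:
        if params is None or not params.covers(spec.variables):
            raise SpecError(
                "standardization requested but params do not cover "
                f"variables {list(spec.variables)}")
    blocks = [np.ones((n, 1))]
    columns: list[tuple[str, int]] = [_INTERCEPT]
    for v in spec.variables:
        x = frame[v].to_numpy(dtype=float)
        if spec.standardize:
            z = (x - params.means[v]) / params.sds[v]
        else:
            z = x
        blocks.append(_expand(z, spec.degree))
        columns.extend((v, k) for k in range(1, spec.degree + 1))
    X = np.hstack(blocks) if n else np.zeros((0, spec.n_columns))
    return DesignMatrix(values=X, columns=columns, spec=spec,
                        params=params if spec.standardize else None)
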