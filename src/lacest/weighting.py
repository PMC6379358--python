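"""Per-variable weighting analysis of a fitted lactate model.

After the Taylor expansion every variable owns several coefficients (one
per polynomial order), but the weighting analysis reports a single signed
number per variable. Two extraction rules are provided:

``first_order`` (default)
    the degree-1 coefficient of the variable — the partial derivative of
    the fitted surface at the standardized cohort mean, i.e. the model's
    local sensitivity to that variable;

``signed_l1``
    sign of the degree-1 coefficient times the sum of absolute
    coefficients across all orders of that variable.

Normalized weights divide each signed weight by the sum of absolute
weights over all variables, so the absolute normalized weights add to 1.
Weights are only meaningful on a common scale, hence the model must have
been fitted on standardized features; the intercept is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import NormalizationError, ScaleError, SpecError
from .regression import FittedModel

__all__ = ["WeightingReport", "variable_weights", "WEIGHT_RULES"]

WEIGHT_RULES = ("first_order", "signed_l1")


@dataclass
class WeightingReport:
    """Signed absolute and normalized weights, one per model variable."""

    variables: tuple[str, ...]
    absolute: dict[str, float]
    normalized: dict[str, float]
    rule: str
    stratum: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": list(self.variables),
            "absolute_weight": [self.absolute[v] for v in self.variables],
            "normalized_weight": [self.normalized[v] for v in self.variables],
            "rule": self.rule,
        })

    def ranking(self) -> list[str]:
        """Variables ordered by decreasing |normalized weight|."""
        return sorted(self.variables,
                      key=lambda v: abs(self.normalized[v]), reverse=True)


def variable_weights(model: FittedModel, rule: str = "first_order"
                     ) -> WeightingReport:
    """Extract one signed weight per variable from the coefficient vector.

    Raises :class:`ScaleError` if the model was fitted on unstandardized
    features and :class:`NormalizationError` if every weight is zero.
    """
    if rule not in WEIGHT_RULES:
        raise SpecError(f"unknown weighting rule {rule!r}; "
                        f"expected one of {list(WEIGHT_RULES)}")
    spec = model.feature_spec
    if spec is None or not spec.standardize or \
            model.standardization_params is None:
        raise ScaleError(
            "weights require a model fitted on standardized features; "
            "coefficients of raw-scale variables conflate units with "
            "importance")
    variables = spec.variables
    if not variables:
        raise SpecError("model has no variables to weight")

    absolute: dict[str, float] = {}
    for v in variables:
        c1 = model.coefficient(v, 1)
        if rule == "first_order":
            absolute[v] = c1
        else:  # signed_l1
            total = sum(abs(model.coefficient(v, k))
                        for k in range(1, spec.degree + 1))
            sign = 0.0 if c1 == 0 else (1.0 if c1 > 0 else -1.0)
            absolute[v] = sign * total

    denom = sum(abs(w) for w in absolute.values())
    if denom == 0.0:
        raise NormalizationError("all weights are zero; cannot normalize")
    normalized = {v: w / denom for v, w in absolute.items()}
    return WeightingReport(variables=tuple(variables), absolute=absolute,
                           normalized=normalized, rule=rule,
                           stratum=model.stratum)
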