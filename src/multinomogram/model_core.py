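"""Multinomial logistic models: linear predictors, probabilities, and the
additive log-probability decomposition.

A fitted multinomial logistic model with K outcome categories and reference
category K relates a covariate vector ``x`` to K-1 log-odds (linear
predictors)

    l_k = alpha_k + beta_k' x,        k = 1, ..., K-1,

and category probabilities

    pi_k = exp(l_k) / (1 + sum_p exp(l_p))      for k != reference,
    pi_ref = 1 / (1 + sum_p exp(l_p)).

Writing ``s = -ln(1 + sum_p exp(l_p))``, the log probability of every
category decomposes additively,

    ln pi_k = l_k + s    (with l_ref := 0),

which is the identity a parallel-scale nomogram renders geometrically: one
straight line through ``l_k`` on one outer axis and ``s`` on the other
crosses the middle axis at ``ln pi_k``.

The model here is *supplied*, not estimated: intercepts and coefficients
come from a published table or an external fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "Covariate",
    "ModelSpec",
    "CovariateProfile",
    "PredictorState",
    "Finding",
    "linear_predictors",
    "s_value",
    "category_probabilities",
    "validate_model",
]


class AlignmentError(ValueError):
    """Profile does not align with the model's covariates."""


class RangeError(ValueError):
    """A value lies outside its declared range and clamping is off."""


class ModelValidationError(ValueError):
    """The model specification fails a hard structural check."""


@dataclass(frozen=True)
class Covariate:
    """One predictor variable.

    ``kind`` is ``"continuous"`` or ``"binary"``; multi-level categorical
    predictors must be pre-coded as binary dummies.  ``low``/``high`` bound
    the clinically relevant range (for binary covariates always 0 and 1);
    the scoring chart and default axis ranges are computed over this box.
    """

    name: str
    kind: Literal["continuous", "binary"] = "continuous"
    unit: str = ""
    low: float = 0.0
    high: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ModelValidationError(
                f"covariate {self.name!r}: kind must be 'continuous' or 'binary', "
                f"got {self.kind!r}"
            )
        if self.kind == "binary" and (self.low, self.high) != (0.0, 1.0):
            raise ModelValidationError(
                f"covariate {self.name!r}: binary covariates must have range [0, 1]"
            )
        if not (np.isfinite(self.low) and np.isfinite(self.high)):
            raise ModelValidationError(f"covariate {self.name!r}: non-finite range")
        if not self.low < self.high:
            raise ModelValidationError(
                f"covariate {self.name!r}: range low ({self.low}) must be < high ({self.high})"
            )


@dataclass(frozen=True)
class ModelSpec:
    """A fitted multinomial logistic model.

    Parameters
    ----------
    categories
        Ordered outcome-category labels, length K >= 2.
    covariates
        J covariate descriptors, ordered as the coefficient columns.
    intercepts
        K-1 intercepts ``alpha_k`` (log-odds vs the reference), ordered as
        the non-reference categories appear in ``categories``.
    coefficients
        (K-1) x J matrix ``beta_jk`` of log-odds per covariate unit; row k
        belongs to the k-th non-reference category, column j to covariate j.
    reference
        Label of the reference category.  Defaults to the last category.
    """

    categories: tuple[str, ...]
    covariates: tuple[Covariate, ...]
    intercepts: np.ndarray
    coefficients: np.ndarray
    reference: str = ""
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(
            self, "intercepts", np.asarray(self.intercepts, dtype=float)
        )
        object.__setattr__(
            self, "coefficients", np.atleast_2d(np.asarray(self.coefficients, dtype=float))
        )
        if not self.reference:
            object.__setattr__(self, "reference", self.categories[-1])
        if len(self.categories) < 2:
            raise ModelValidationError("need K >= 2 outcome categories")
        if len(set(self.categories)) != len(self.categories):
            raise ModelValidationError("duplicate category labels")
        if self.reference not in self.categories:
            raise ModelValidationError(
                f"reference category {self.reference!r} not among categories"
            )
        if len(self.covariates) < 1:
            raise ModelValidationError("need J >= 1 covariates")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ModelValidationError("duplicate covariate names")

    # -- derived views ----------------------------------------------------

    @property
    def K(self) -> int:
        return len(self.categories)

    @property
    def J(self) -> int:
        return len(self.covariates)

    @property
    def reference_index(self) -> int:
        return self.categories.index(self.reference)

    @property
    def nonreference_categories(self) -> tuple[str, ...]:
        return tuple(c for c in self.categories if c != self.reference)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    @property
    def lows(self) -> np.ndarray:
        return np.array([c.low for c in self.covariates])

    @property
    def highs(self) -> np.ndarray:
        return np.array([c.high for c in self.covariates])

    def fingerprint(self) -> str:
        """Stable hash of the model's defining numbers and labels."""
        import hashlib

        h = hashlib.sha256()
        h.update(repr(self.categories).encode())
        h.update(self.reference.encode())
        for c in self.covariates:
            h.update(f"{c.name}|{c.kind}|{c.low!r}|{c.high!r}".encode())
        h.update(self.intercepts.tobytes())
        h.update(self.coefficients.tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class CovariateProfile:
    """One subject's covariate values, aligned to a model's covariate order."""

    x: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float).ravel())

    @classmethod
    def from_mapping(cls, model: ModelSpec, values: dict) -> "CovariateProfile":
        missing = [n for n in model.covariate_names if n not in values]
        if missing:
            raise AlignmentError(f"profile missing covariates: {missing}")
        extra = [n for n in values if n not in model.covariate_names]
        if extra:
            raise AlignmentError(f"profile has unknown covariates: {extra}")
        return cls(np.array([float(values[n]) for n in model.covariate_names]))


@dataclass(frozen=True)
class PredictorState:
    """The full additive decomposition for one profile.

    ``l`` holds the K-1 linear predictors (non-reference category order),
    ``s`` the shared log normalizer, ``o = ln pi`` and ``pi`` the K category
    log-probabilities and probabilities in model category order.
    """

    l: np.ndarray
    s: float
    o: np.ndarray
    pi: np.ndarray
    categories: tuple[str, ...]


@dataclass(frozen=True)
class Finding:
    severity: Literal["error", "warning"]
    message: str


def _aligned_x(model: ModelSpec, profile: CovariateProfile, clamp: bool) -> np.ndarray:
    x = profile.x
    if x.shape != (model.J,):
        raise AlignmentError(
            f"profile has {x.size} values but model has {model.J} covariates"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("profile contains non-finite values")
    lo, hi = model.lows, model.highs
    if clamp:
        return np.clip(x, lo, hi)
    bad = (x < lo) | (x > hi)
    if bad.any():
        j = int(np.argmax(bad))
        c = model.covariates[j]
        raise RangeError(
            f"covariate {c.name!r} value {x[j]} outside declared range "
            f"[{c.low}, {c.high}] (pass clamp=True to truncate)"
        )
    return x


def linear_predictors(
    model: ModelSpec, profile: CovariateProfile, *, clamp: bool = False
) -> np.ndarray:
    """Evaluate the K-1 linear predictors ``l_k = alpha_k + beta_k' x``.

    Returned in the model's non-reference category order.  Out-of-range
    covariate values raise :class:`RangeError` unless ``clamp=True``.
    """
    if model.intercepts.shape != (model.K - 1,):
        raise ModelValidationError(
            f"expected {model.K - 1} intercepts, got {model.intercepts.shape}"
        )
    if model.coefficients.shape != (model.K - 1, model.J):
        raise ModelValidationError(
            f"expected coefficient matrix of shape ({model.K - 1}, {model.J}), "
            f"got {model.coefficients.shape}"
        )
    if not (np.all(np.isfinite(model.intercepts)) and np.all(np.isfinite(model.coefficients))):
        raise ModelValidationError("model has non-finite intercepts or coefficients")
    x = _aligned_x(model, profile, clamp)
    return model.intercepts + model.coefficients @ x


def s_value(l: Sequence[float] | np.ndarray) -> float:
    """The shared log normalizer ``s = -ln(1 + sum_p exp(l_p))``.

    Computed by log-sum-exp over ``(0, l_1, ..., l_{K-1})`` so extreme
    linear predictors neither overflow nor lose the leading 1.  Always
    negative for finite ``l``.
    """
    l = np.asarray(l, dtype=float)
    if not np.all(np.isfinite(l)):
        raise ValueError("linear predictors must be finite")
    return float(-logsumexp(np.concatenate(([0.0], l))))


def category_probabilities(
    model: ModelSpec, profile: CovariateProfile, *, clamp: bool = False
) -> PredictorState:
    """Probabilities of all K categories plus the l/s/o decomposition.

    ``pi_k = exp(l_k + s)`` for non-reference categories and
    ``pi_ref = exp(s)``; the probabilities sum to one by construction.
    """
    l = linear_predictors(model, profile, clamp=clamp)
    s = s_value(l)
    o = np.empty(model.K)
    ref = model.reference_index
    nonref = [i for i in range(model.K) if i != ref]
    o[nonref] = l + s
    o[ref] = s
    pi = np.exp(o)
    return PredictorState(l=l, s=s, o=o, pi=pi, categories=model.categories)


def validate_model(model: ModelSpec) -> list[Finding]:
    """Structural and numerical checks, returned as findings, not raised.

    Errors: wrong intercept/coefficient dimensions, non-finite values.
    Warnings: a covariate whose coefficients are all zero (it carries no
    points on the scoring chart), and the degenerate-but-allowed K=2 case
    where the multinomial model is an ordinary binary logistic model.
    """
    findings: list[Finding] = []
    Km1 = model.K - 1
    if model.intercepts.shape != (Km1,):
        findings.append(
            Finding("error", f"expected {Km1} intercepts, got {model.intercepts.shape[0]}")
        )
    if model.coefficients.shape != (Km1, model.J):
        findings.append(
            Finding(
                "error",
                f"expected coefficient matrix ({Km1}, {model.J}), got "
                f"{model.coefficients.shape}",
            )
        )
    if not np.all(np.isfinite(model.intercepts)):
        findings.append(Finding("error", "non-finite intercept"))
    if not np.all(np.isfinite(model.coefficients)):
        findings.append(Finding("error", "non-finite coefficient"))
    if model.coefficients.shape == (Km1, model.J):
        for j, c in enumerate(model.covariates):
            if np.all(model.coefficients[:, j] == 0.0):
                findings.append(
                    Finding("warning", f"covariate {c.name!r} carries no points (all-zero coefficients)")
                )
    if model.K == 2:
        findings.append(
            Finding("warning", "K=2: model reduces to binary logistic regression")
        )
    return findings
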