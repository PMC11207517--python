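"""Hierarchical multi-criteria scoring of fruit quality: AHP x entropy x TOPSIS.

The comprehensive quality of a fruit sample is scored in four steps:

1. factor (criterion-group) weights from the analytic hierarchy process
   (AHP) — either a 1-9 scale pairwise judgment matrix or direct weights;
2. objective sub-factor weights from the entropy method on the min-max
   standardized data (criteria whose standardized distribution carries more
   information, i.e. lower entropy, weigh more), normalized within each
   factor;
3. combined weights = factor weight x within-factor entropy weight;
4. TOPSIS closeness: options are scored by their relative Euclidean
   distance to the ideal vs the anti-ideal vector of the weighted,
   direction-aware standardized matrix.

Entropy weights are computed on the direction-free (benefit-form) min-max
standardization; criterion direction (only organic acid is treated as a
cost by default) enters when the TOPSIS matrix is standardized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import InputError

#: Criterion -> factor grouping of the evaluation hierarchy.
DEFAULT_FACTORS = {
    "ci": "appearance",
    "firmness": "appearance",
    "ssc": "taste",
    "oac": "taste",
    "ssc_oac": "taste",
    "lycopene": "nutrition",
    "vc": "nutrition",
}

#: AHP factor weights used in the study (appearance, taste, nutrition).
DEFAULT_FACTOR_WEIGHTS = {"appearance": 0.158, "taste": 0.680, "nutrition": 0.162}

#: Criterion directions; anything absent is a benefit criterion.
DEFAULT_DIRECTIONS = {"oac": "cost"}

#: Saaty random consistency indices by matrix order.
SAATY_RI = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45}


@dataclass(frozen=True)
class WeightVector:
    """Labelled non-negative weights summing to one (within ``atol``)."""

    labels: tuple
    weights: np.ndarray
    atol: float = 1e-6

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if len(self.labels) != len(self.weights):
            raise InputError("labels and weights differ in length")
        if np.any(self.weights < 0):
            raise InputError("weights must be non-negative")
        total = float(self.weights.sum())
        if abs(total - 1.0) > self.atol:
            raise InputError(f"weights sum to {total}, not 1 (atol={self.atol})")

    def __len__(self) -> int:
        return len(self.labels)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.labels))

    def __getitem__(self, label) -> float:
        return float(self.weights[self.labels.index(label)])


@dataclass(frozen=True)
class JudgmentMatrix:
    """Positive reciprocal AHP pairwise-comparison matrix on the 1-9 scale."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.labels)
        if values.shape != (n, n):
            raise InputError(f"judgment matrix must be {n}x{n}")
        if not (2 <= n <= 9):
            raise InputError("AHP supports 2 to 9 criteria")
        if np.any(values <= 0):
            raise InputError("judgment matrix entries must be positive")
        if not np.allclose(np.diag(values), 1.0, atol=1e-9):
            raise InputError("judgment matrix diagonal must be 1")
        if not np.allclose(values * values.T, 1.0, atol=1e-9):
            raise InputError("judgment matrix must be reciprocal")


@dataclass(frozen=True)
class AhpResult:
    weights: WeightVector
    lambda_max: float
    consistency_index: float
    consistency_ratio: float

    @property
    def consistent(self) -> bool:
        return self.consistency_ratio <= 0.1


def ahp_weights(matrix: JudgmentMatrix, tol: float = 1e-12, max_iter: int = 10_000) -> AhpResult:
    """Principal-eigenvector weights of a judgment matrix, with Saaty's consistency ratio.

    The eigenvector is found by power iteration; CR = ((lambda_max - n) /
    (n - 1)) / RI(n), and CR <= 0.1 is the conventional consistency pass.
    """
    A = matrix.values
    n = A.shape[0]
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        w_new = A @ w
        w_new /= w_new.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    lambda_max = float(np.mean((A @ w) / w))
    ci = (lambda_max - n) / (n - 1) if n > 1 else 0.0
    cr = 0.0 if n <= 2 else ci / SAATY_RI[n]
    return AhpResult(
        weights=WeightVector(matrix.labels, w),
        lambda_max=lambda_max,
        consistency_index=float(ci),
        consistency_ratio=float(cr),
    )


def minmax_standardize(frame: pd.DataFrame, directions: dict | None = None) -> pd.DataFrame:
    """Column-wise min-max standardization to [0, 1] with optional cost reversal.

    Benefit columns map min -> 0 and max -> 1; cost columns (per
    ``directions``) are reversed so that "better" is always larger.
    """
    directions = directions or {}
    values = frame.to_numpy(dtype=float)
    lo, hi = values.min(axis=0), values.max(axis=0)
    constant = hi == lo
    if np.any(constant):
        bad = list(frame.columns[constant])
        raise InputError(f"constant columns cannot be standardized: {bad}")
    r = (values - lo) / (hi - lo)
    for j, col in enumerate(frame.columns):
        if directions.get(col, "benefit") == "cost":
            r[:, j] = 1.0 - r[:, j]
    return pd.DataFrame(r, index=frame.index, columns=frame.columns)


def entropy_weights(standardized: pd.DataFrame) -> WeightVector:
    """Entropy-method objective weights from a standardized (non-negative) matrix.

    Column shares p_ij are the column-normalized standardized values; the
    information entropy e_j = -(1/ln n) sum p ln p (with 0 ln 0 := 0) turns
    into weights w_j = (1 - e_j) / sum(1 - e_k).
    """
    r = standardized.to_numpy(dtype=float)
    if np.any(r < 0):
        raise InputError("standardized values must be non-negative")
    colsum = r.sum(axis=0)
    if np.any(colsum == 0):
        bad = list(standardized.columns[colsum == 0])
        raise InputError(f"all-zero columns have undefined entropy: {bad}")
    p = r / colsum
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    e = -plogp.sum(axis=0) / np.log(len(standardized))
    info = 1.0 - e
    if info.sum() <= 0:
        raise InputError("all columns are maximally entropic; weights undefined")
    return WeightVector(tuple(standardized.columns), info / info.sum())


def combined_weights(factor: WeightVector, subfactors: dict) -> WeightVector:
    """Multiply factor weights into per-factor sub-weights; grand total one.

    ``subfactors`` maps each factor label to the :class:`WeightVector` of
    its criteria (summing to one within the factor).
    """
    if set(subfactors) != set(factor.labels):
        raise InputError(
            f"sub-factor groups {sorted(subfactors)} do not match factors {sorted(factor.labels)}"
        )
    labels, values = [], []
    for name in factor.labels:
        sub = subfactors[name]
        labels.extend(sub.labels)
        values.extend(factor[name] * sub.weights)
    total = float(np.sum(values))
    return WeightVector(tuple(labels), np.asarray(values) / total, atol=5e-3)


def topsis_closeness(standardized: pd.DataFrame, weights) -> pd.DataFrame:
    """TOPSIS relative closeness of each option to the ideal solution.

    The weighted matrix Z = r_ij w_j is compared against the ideal (column
    maxima) and anti-ideal (column minima) vectors through Euclidean
    distances D+ and D-; the closeness C = D- / (D+ + D-) lies in [0, 1].
    Returns a frame with d_plus, d_minus, closeness and dense rank (1 best).
    """
    if isinstance(weights, WeightVector):
        weights = weights.as_series().reindex(standardized.columns).to_numpy()
    weights = np.asarray(weights, dtype=float)
    if len(weights) != standardized.shape[1] or np.any(np.isnan(weights)):
        raise InputError("weights do not match the criteria columns")
    Z = standardized.to_numpy(dtype=float) * weights
    ideal, anti = Z.max(axis=0), Z.min(axis=0)
    if np.allclose(ideal, anti):
        raise InputError("degenerate matrix: ideal and anti-ideal coincide")
    d_plus = np.sqrt(((Z - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((Z - anti) ** 2).sum(axis=1))
    both_zero = (d_plus == 0) & (d_minus == 0)
    if np.any(both_zero):
        raise InputError("option(s) equal to both ideal and anti-ideal")
    closeness = d_minus / (d_plus + d_minus)
    out = pd.DataFrame(
        {"d_plus": d_plus, "d_minus": d_minus, "closeness": closeness},
        index=standardized.index,
    )
    out["rank"] = out["closeness"].rank(ascending=False, method="min").astype(int)
    return out


class ComprehensiveQualityScorer(TransformerMixin, BaseEstimator):
    """AHP x entropy x TOPSIS scorer for fruit-quality criterion matrices.

    ``fit`` learns the column ranges, the entropy sub-factor weights and the
    ideal/anti-ideal vectors from a calibration matrix (rows = samples,
    columns = criteria); ``transform`` returns the TOPSIS closeness of rows
    scored against that calibration.  ``fit_transform`` therefore gives the
    in-sample comprehensive quality scores.

    Parameters
    ----------
    factor_weights : mapping factor -> weight, or None
        Subjective (AHP) factor weights; default is the study preset
        (appearance 0.158, taste 0.680, nutrition 0.162).  Use
        :func:`ahp_weights` to derive one from a judgment matrix.
    directions : mapping criterion -> {"benefit", "cost"}, or None
        Default treats organic acid as the only cost criterion.
    factors : mapping criterion -> factor, or None
        Hierarchy grouping; default is the appearance/taste/nutrition split.
    """

    def __init__(self, factor_weights=None, directions=None, factors=None):
        self.factor_weights = factor_weights
        self.directions = directions
        self.factors = factors

    def _resolved(self):
        factors = dict(DEFAULT_FACTORS if self.factors is None else self.factors)
        directions = dict(DEFAULT_DIRECTIONS if self.directions is None else self.directions)
        fw = dict(DEFAULT_FACTOR_WEIGHTS if self.factor_weights is None else self.factor_weights)
        if set(fw) != set(factors.values()):
            raise InputError("factor_weights labels do not match the hierarchy factors")
        return factors, directions, fw

    def fit(self, X: pd.DataFrame, y=None):
        factors, directions, fw = self._resolved()
        columns = [c for c in X.columns if c in factors]
        if not columns:
            raise InputError("no criterion columns found")
        if len(X) < 2:
            raise InputError("need at least two options to score")
        data = X[columns]
        self.criteria_ = tuple(columns)
        self.min_ = data.min(axis=0)
        self.max_ = data.max(axis=0)

        # entropy on the direction-free standardization; directions apply later
        benefit_std = minmax_standardize(data, directions=None)
        self.entropy_weights_ = entropy_weights(benefit_std)

        sub = {}
        series = self.entropy_weights_.as_series()
        for factor in fw:
            members = [c for c in columns if factors[c] == factor]
            if not members:
                raise InputError(f"factor {factor!r} has no criteria in the data")
            w = series[members].to_numpy()
            sub[factor] = WeightVector(tuple(members), w / w.sum())
        self.subfactor_weights_ = sub
        self.combined_weights_ = combined_weights(
            WeightVector(tuple(fw), np.array([fw[f] for f in fw])), sub
        )

        std = self._standardize(data, directions)
        w = self.combined_weights_.as_series().reindex(columns).to_numpy()
        Z = std.to_numpy() * w
        self.ideal_ = Z.max(axis=0)
        self.anti_ideal_ = Z.min(axis=0)
        self.directions_ = directions
        self.n_features_in_ = len(columns)
        return self

    def _standardize(self, data: pd.DataFrame, directions) -> pd.DataFrame:
        span = (self.max_ - self.min_)
        r = (data - self.min_) / span
        r = r.clip(0.0, 1.0)
        for col in data.columns:
            if directions.get(col, "benefit") == "cost":
                r[col] = 1.0 - r[col]
        return r

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """TOPSIS closeness of each row of ``X`` against the fitted calibration."""
        return self.score_frame(X)["closeness"].to_numpy()

    def score_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "criteria_"):
            raise InputError("scorer is not fitted")
        data = X[list(self.criteria_)]
        std = self._standardize(data, self.directions_)
        w = self.combined_weights_.as_series().reindex(list(self.criteria_)).to_numpy()
        Z = std.to_numpy() * w
        d_plus = np.sqrt(((Z - self.ideal_) ** 2).sum(axis=1))
        d_minus = np.sqrt(((Z - self.anti_ideal_) ** 2).sum(axis=1))
        if np.any((d_plus == 0) & (d_minus == 0)):
            raise InputError("degenerate option equal to both ideal and anti-ideal")
        out = pd.DataFrame(
            {"d_plus": d_plus, "d_minus": d_minus, "closeness": d_minus / (d_plus + d_minus)},
            index=X.index,
        )
        out["rank"] = out["closeness"].rank(ascending=False, method="min").astype(int)
        return out


def comprehensive_quality(data, factor_weights=None, directions=None, factors=None) -> pd.DataFrame:
    """Score options by the full AHP x entropy x TOPSIS pipeline.

    ``data`` is either a criteria DataFrame or a list of quality records
    (anything exposing the criterion attributes and a ``label``).  Returns
    the TOPSIS frame (d_plus, d_minus, closeness, rank) indexed by option.
    """
    if not isinstance(data, pd.DataFrame):
        from .quality import records_to_frame

        data = records_to_frame(data)
    scorer = ComprehensiveQualityScorer(
        factor_weights=factor_weights, directions=directions, factors=factors
    )
    scorer.fit(data)
    return scorer.score_frame(data)
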