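"""The composite accessibility index: normalization, combination, deciles.

Per facility type, potential accessibility distances are mapped to standard
normal scores. The default is the rank-based inverse-normal transform with the
Blom offset, z_i = Phi^-1((r_i - 3/8) / (n + 1/4)) on midranks, which delivers
a centered, unit-variance, normally shaped score even for strongly skewed
distance distributions; plain z-scoring is available as an alternative.

The index is a signed linear combination of the per-type scores. With the
default sign of -1, shorter weighted distances give a larger index, i.e.
better accessibility, and decile 1 collects the best-served areas.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ScaleAccessError

NORMALIZATIONS = ("rank_normal", "zscore")


def normal_scores(values, method: str = "rank_normal") -> np.ndarray:
    """Standardized scores of one facility type's PAD vector.

    ``rank_normal``: Blom rank-based inverse-normal transform on midranks —
    strictly monotone in the input, mean 0 by symmetry, SD equal to the
    theoretical Blom-score SD when values are distinct.
    ``zscore``: ordinary (x - mean) / sd standardization.

    Raises ``DegenerateInputError`` on fewer than 2 values or a constant
    vector (no ordering information to standardize).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise DegenerateInputError(f"normal_scores needs a 1-d vector of n >= 2, got n={x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("normal_scores: constant input vector")
    if method == "rank_normal":
        r = stats.rankdata(x, method="average")  # midranks for ties
        return stats.norm.ppf((r - 0.375) / (len(x) + 0.25))
    if method == "zscore":
        return (x - x.mean()) / x.std(ddof=1)
    raise ScaleAccessError(f"unknown normalization {method!r}; choose from {NORMALIZATIONS}")


def score_table(pads: pd.DataFrame, method: str = "rank_normal") -> pd.DataFrame:
    """Wide z-score table (index area_id, one column per facility type)."""
    wide = pads.pivot(index="area_id", columns="facility_type", values="pad")
    if wide.isna().any().any():
        missing = wide.stack(dropna=False)
        missing = missing[missing.isna()].index[0]
        raise ScaleAccessError(f"missing pad for (area, type) {missing}")
    z = pd.DataFrame({t: normal_scores(wide[t].to_numpy(), method) for t in wide.columns},
                     index=wide.index)
    z.columns.name = "facility_type"
    return z


def combine(
    z: pd.DataFrame,
    weights: Mapping[str, float] | None = None,
    sign_convention: int = -1,
) -> pd.Series:
    """Signed linear combination of per-type z scores into one index value.

    value_i = sign * sum_k w_k z_ik, with unit weights by default. Weights
    must be non-negative and not all zero; a missing z cell raises.
    """
    if sign_convention not in (-1, 1):
        raise ScaleAccessError(f"sign_convention must be -1 or 1, got {sign_convention}")
    if z.isna().any().any():
        raise ScaleAccessError("combine: missing z score cell")
    if weights is None:
        w = pd.Series(1.0, index=z.columns)
    else:
        unknown = set(weights) - set(z.columns)
        if unknown:
            raise ScaleAccessError(f"combine: weights given for unknown types {sorted(unknown)}")
        w = pd.Series({t: float(weights.get(t, 1.0)) for t in z.columns})
    if (w < 0).any() or w.sum() == 0:
        raise ScaleAccessError("combine: weights must be >= 0 and not all zero")
    out = sign_convention * (z * w).sum(axis=1)
    out.name = "scale_value"
    return out


def decile_classify(values) -> np.ndarray:
    """Decile labels 1..10, label 1 = top decile (highest values).

    Boundaries sit at the empirical quantiles 0.1..0.9 of the value
    distribution; a value tied with a boundary joins the better class. A
    fully constant vector collapses to a single class with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 10:
        raise ScaleAccessError(f"decile_classify needs n >= 10 values, got n={v.size}")
    if np.ptp(v) == 0:
        warnings.warn("decile_classify: constant values collapse to a single class",
                      stacklevel=2)
        return np.ones(len(v), dtype=int)
    n = len(v)
    # A value is below the boundary at quantile 1 - j/10 (linear interpolation,
    # position (n-1)(10-j)/10) iff its max-tie rank is below the boundary's
    # index, so the labels follow from integer rank arithmetic alone — no
    # floating-point interpolation can flip a knife-edge case.
    pos = stats.rankdata(v, method="max").astype(int) - 1
    thresholds = []
    for j in range(1, 10):
        f, g = divmod((n - 1) * (10 - j), 10)
        thresholds.append(f + (1 if g else 0))
    labels = 1 + (pos[:, None] < np.array(thresholds)[None, :]).sum(axis=1)
    return labels.astype(int)


def build_results(
    areas: pd.DataFrame,
    pads: pd.DataFrame,
    normalization: str = "rank_normal",
    weights: Mapping[str, float] | None = None,
    sign_convention: int = -1,
) -> pd.DataFrame:
    """Assemble the per-area result table: pads, z scores, index value, decile."""
    z = score_table(pads, normalization)
    value = combine(z, weights, sign_convention)
    wide_pad = pads.pivot(index="area_id", columns="facility_type", values="pad")
    out = pd.concat([wide_pad.add_prefix("pad_"), z.add_prefix("z_")], axis=1)
    out["scale_value"] = value
    out["decile"] = decile_classify(value.to_numpy())
    out = out.reset_index()
    keep = [c for c in ("x", "y", "population", "iris_id", "commune_id", "region_id")
            if c in areas.columns]
    return out.merge(areas[["area_id", *keep]], on="area_id", validate="1:1")
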