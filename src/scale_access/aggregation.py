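"""Multiscalar aggregation of the per-area index and between-version agreement.

Because the index is computed at the residential-area level, it can be rolled
up to any coarser unit (IRIS, commune, region) under four criteria: minimum,
maximum, mean, and population-weighted mean. Each (level, criterion) version
is decile-classified against its own distribution; agreement between versions
is the percentage of units that land in the same decile under both.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .errors import ScaleAccessError
from .index import decile_classify

LEVELS = {"iris": "iris_id", "commune": "commune_id", "region": "region_id"}
CRITERIA = ("min", "max", "mean", "weighted_mean")


def aggregate(
    results: pd.DataFrame,
    level: str,
    criterion: str,
    classify: bool = True,
) -> pd.DataFrame:
    """Per-unit statistic of ``scale_value`` over the unit's member areas.

    ``results`` must carry the unit id column for the level (and
    ``population`` for weighted_mean). A unit whose total population is zero
    falls back from weighted mean to the plain mean, with a warning.
    With ``classify=True`` each version gets deciles from its own distribution
    (needs >= 10 units).
    """
    if level not in LEVELS:
        raise ScaleAccessError(f"unknown level {level!r}; choose from {sorted(LEVELS)}")
    if criterion not in CRITERIA:
        raise ScaleAccessError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")
    unit_col = LEVELS[level]
    if unit_col not in results.columns:
        raise ScaleAccessError(f"results table lacks {unit_col!r}")
    grouped = results.groupby(unit_col)["scale_value"]
    if criterion == "min":
        value = grouped.min()
    elif criterion == "max":
        value = grouped.max()
    elif criterion == "mean":
        value = grouped.mean()
    else:
        if "population" not in results.columns:
            raise ScaleAccessError("weighted_mean needs a population column")

        def wmean(g: pd.DataFrame) -> float:
            w = g["population"].to_numpy(float)
            v = g["scale_value"].to_numpy(float)
            if w.sum() == 0:
                warnings.warn(
                    f"unit {g.name!r} has zero total population; weighted mean "
                    "falls back to the plain mean", stacklevel=2)
                return float(v.mean())
            return float((w * v).sum() / w.sum())

        value = results.groupby(unit_col)[["population", "scale_value"]].apply(wmean)
    out = value.rename("value").reset_index().rename(columns={unit_col: "unit_id"})
    out = out.sort_values("unit_id", ignore_index=True)
    out.insert(1, "level", level)
    out.insert(2, "criterion", criterion)
    if classify:
        if len(out) >= 10:
            out["decile"] = decile_classify(out["value"].to_numpy())
        else:
            warnings.warn(
                f"level {level!r} has only {len(out)} units; deciles are undefined "
                "below 10 and are left missing", stacklevel=2)
            out["decile"] = np.nan
    return out


def agreement(deciles_a: pd.Series, deciles_b: pd.Series) -> float:
    """Percentage of units with identical decile labels under two versions.

    Both series are indexed by unit_id; mismatched unit sets raise.
    """
    if set(deciles_a.index) != set(deciles_b.index):
        raise ScaleAccessError("agreement: the two versions cover different unit sets")
    b = deciles_b.reindex(deciles_a.index)
    return float(100.0 * (deciles_a == b).mean())


def agreement_matrix(versions: dict[str, pd.Series], level: str) -> pd.DataFrame:
    """Pairwise decile agreement between aggregation versions at one level.

    ``versions`` maps criterion name -> decile Series indexed by unit_id.
    The output is symmetric with a 100% diagonal, in long form
    (level, criterion_a, criterion_b, percent_identical).
    """
    names = sorted(versions)
    rows = []
    for a, b in itertools.product(names, names):
        pct = 100.0 if a == b else agreement(versions[a], versions[b])
        rows.append((level, a, b, pct))
    return pd.DataFrame(rows, columns=["level", "criterion_a", "criterion_b",
                                       "percent_identical"])


def aggregate_all(
    results: pd.DataFrame,
    levels=("iris", "commune"),
    criteria=CRITERIA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All (level, criterion) versions plus the full agreement table."""
    agg_frames, agr_frames = [], []
    for level in levels:
        versions = {}
        for criterion in criteria:
            table = aggregate(results, level, criterion, classify=True)
            agg_frames.append(table)
            versions[criterion] = table.set_index("unit_id")["decile"]
        if all(v.notna().all() for v in versions.values()):
            agr_frames.append(agreement_matrix(versions, level))
    agr = (pd.concat(agr_frames, ignore_index=True) if agr_frames
           else pd.DataFrame(columns=["level", "criterion_a", "criterion_b",
                                      "percent_identical"]))
    return pd.concat(agg_frames, ignore_index=True), agr
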