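"""Two-condition gel spot differential-abundance filtering.

Spot volumes from two growth conditions (e.g. atmospheric vs. high
hydrostatic pressure) are normalised per gel to relative volumes, replicates
are averaged, and the differential abundance DA = larger / smaller relative
volume is computed per spot. A spot is flagged significant when DA meets the
ratio threshold (inclusive >= 1.5 by default) or when it was quantified in
only one condition (qualitative presence/absence difference).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("spot_id", "condition", "replicate", "volume")


def differential_abundance(
    table: pd.DataFrame,
    threshold: float = 1.5,
    strict: bool = False,
    normalize: bool = True,
) -> pd.DataFrame:
    """Apply the differential-abundance ratio rule to a long-format table.

    ``table`` needs columns ``spot_id, condition, replicate, volume`` with
    exactly two condition labels; volumes must be positive (a spot absent
    from a gel is simply missing its row). With ``normalize`` (default) each
    gel's volumes are divided by that gel's total, so relative volumes per
    gel sum to 1; replicate relative volumes are then averaged per
    condition.

    ``strict`` switches the significance rule from DA >= threshold to
    DA > threshold.

    Returns a wide table indexed by spot id with the two per-condition
    relative volumes, ``da``, ``direction`` (condition with higher
    abundance), ``significant`` and ``missing`` (quantified in one condition
    only; DA undefined, flagged significant).
    """
    missing_cols = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"table missing columns {sorted(missing_cols)}")
    if threshold < 1.0 or not math.isfinite(threshold):
        raise ValueError("threshold must be finite and >= 1")
    conditions = sorted(table["condition"].unique().tolist())
    if len(conditions) != 2:
        raise ValueError(f"expected exactly two conditions, got {conditions}")
    if (table["volume"] <= 0).any() or not np.isfinite(table["volume"]).all():
        raise ValueError("volumes must be positive and finite")

    work = table.copy()
    if normalize:
        totals = work.groupby(["condition", "replicate"])["volume"].transform("sum")
        work["volume"] = work["volume"] / totals
    rel = (
        work.groupby(["spot_id", "condition"])["volume"]
        .mean()
        .unstack("condition")
    )
    c0, c1 = conditions
    both = rel[c0].notna() & rel[c1].notna()
    if (~rel[c0].notna() & ~rel[c1].notna()).any():
        raise ValueError("spot missing in both conditions")

    da = pd.Series(np.nan, index=rel.index)
    hi = np.maximum(rel[c0], rel[c1])
    lo = np.minimum(rel[c0], rel[c1])
    da[both] = (hi / lo)[both]
    direction = pd.Series("", index=rel.index, dtype=object)
    direction[rel[c0] >= rel[c1]] = c0
    direction[rel[c1] > rel[c0]] = c1
    direction[rel[c0] == rel[c1]] = ""
    missing = ~both
    direction[missing & rel[c0].notna()] = c0
    direction[missing & rel[c1].notna()] = c1
    # ratios of normalised volumes can miss the threshold by float round-off
    # (e.g. 0.6/0.4 != 1.5 exactly), so ties are resolved within 1e-9 relative
    at_threshold = np.isclose(da, threshold, rtol=1e-9)
    if strict:
        significant = ((da > threshold) & ~at_threshold) | missing
    else:
        significant = (da > threshold) | at_threshold | missing

    out = pd.DataFrame(
        {
            f"rel_{c0}": rel[c0],
            f"rel_{c1}": rel[c1],
            "da": da,
            "direction": direction,
            "significant": significant,
            "missing": missing,
        }
    )
    out.index.name = "spot_id"
    return out
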