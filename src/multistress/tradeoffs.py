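"""Ternary trade-off coordinates among the three life-history traits.

Each trait is z-scored across the whole dataset and placed into 100
percentile bins (average ranks, so ties share a bin). An individual's
ternary coordinate is its three bins normalized to sum to 1; group points
are the mean of individual coordinates per population x arm, renormalized.
The construction depends only on ranks, so it is invariant to any strictly
increasing transform of a trait.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataio import TRAITS, ValidationError, arm_codes

COORD_NAMES = {"fecundity": "f_fecundity", "size_mm": "f_size", "age_days": "f_age"}


def percentile_bins(values: np.ndarray) -> np.ndarray:
    """Assign each value to one of 100 percentile bins (1..100)."""
    ranks = rankdata(values, method="average")
    return np.clip(np.ceil(100.0 * ranks / len(values)), 1, 100).astype(int)


def ternary_coordinates(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ternary coordinates per population x arm.

    Individuals missing any of the three traits are excluded. Raises
    :class:`~multistress.dataio.ValidationError` if a trait is constant
    (percentile bins undefined) or no complete-case record exists.
    Output columns: ``population,arm,f_fecundity,f_size,f_age,n``.
    """
    data = records.copy()
    data["arm"] = arm_codes(data)
    data = data.dropna(subset=list(TRAITS))
    if data.empty:
        raise ValidationError("no records with all three traits non-missing")

    bins = {}
    for trait in TRAITS:
        vals = data[trait].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            raise ValidationError(f"trait {trait!r} is constant; percentiles undefined")
        z = (vals - vals.mean()) / vals.std(ddof=1)  # rank-neutral, kept for fidelity
        bins[trait] = percentile_bins(z)

    binmat = np.column_stack([bins[t] for t in TRAITS]).astype(float)
    coords = binmat / binmat.sum(axis=1, keepdims=True)
    for i, trait in enumerate(TRAITS):
        data[COORD_NAMES[trait]] = coords[:, i]

    rows = []
    cols = [COORD_NAMES[t] for t in TRAITS]
    for (pop, arm), grp in data.groupby(["population", "arm"], observed=True):
        mean = grp[cols].mean().to_numpy()
        mean = mean / mean.sum()
        rows.append({"population": pop, "arm": arm,
                     **dict(zip(cols, mean)), "n": len(grp)})
    out = pd.DataFrame(rows).sort_values(["population", "arm"]).reset_index(drop=True)
    return out
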