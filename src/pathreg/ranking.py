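"""Shared regulator-ranking construction used by both inference engines.

A ranking is a DataFrame with columns ``rank, tf_id, connectivity, n_triplets,
strength, method``.  ``connectivity`` counts distinct pathway genes a TF is
linked to ("interference frequency"); ties are broken by the number of
supporting significant triplets, then mean interaction strength, then TF ID.
The SPLS engine has no triplet notion and reports ``n_triplets = 0``, so its
ties fall through to strength (sum of absolute coefficients) directly.
"""

from __future__ import annotations

import pandas as pd

RANKING_SORT_KEYS = ["connectivity", "n_triplets", "strength", "tf_id"]


def build_ranking(records: pd.DataFrame, top_k: int, method: str) -> pd.DataFrame:
    """Sort per-TF records into a ranking and truncate to ``top_k``.

    Ordering: connectivity desc, n_triplets desc, strength desc, tf_id asc;
    ranks are consecutive from 1.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    frame = records.copy()
    for col, default in (("n_triplets", 0), ("strength", 0.0)):
        if col not in frame.columns:
            frame[col] = default
    if frame.empty:
        frame = pd.DataFrame(
            columns=["rank", "tf_id", "connectivity", "n_triplets", "strength", "method"]
        )
        return frame
    frame = frame.sort_values(
        RANKING_SORT_KEYS,
        ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    frame = frame.head(top_k).copy()
    frame.insert(0, "rank", range(1, len(frame) + 1))
    frame["method"] = method
    return frame.loc[:, ["rank", "tf_id", "connectivity", "n_triplets", "strength", "method"]]
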