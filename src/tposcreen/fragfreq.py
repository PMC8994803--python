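"""Class-conditional substructure frequency analysis.

For a substructure key and a compound group ``x`` the frequency statistic is

    freq_x = (f_x / C_x) / (f / C) = (f_x * C) / (f * C_x)

where ``f_x`` and ``C_x`` are the fragment and compound counts inside group
``x`` and ``f``, ``C`` the same over the whole dataset.  ``freq_x > 1`` means
the fragment is over-represented in group ``x`` relative to the dataset.

By default "number of fragments" is counted presence-based (a compound with
at least one match contributes 1 to ``f_x``), which makes a fragment with
identical prevalence in every group score exactly 1 everywhere; occurrence
counting (summing distinct matches) is available via ``counting``.

A key is called an **active substructure** when its frequency in the most
active group exceeds 1.2 and the ratio of that frequency to the inactive
group's exceeds 1.2 (a zero inactive frequency with a positive active one
counts as active, ratio +inf).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = [
    "frequency_table",
    "substructure_frequency",
    "identify_active_substructures",
]


def _counts_frame(counts: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(counts, FeatureMatrix):
        df = counts.to_dataframe()
        # strip the block prefix from concatenated/sub matrices for readability
        df.columns = [c.split(":", 1)[1] if c.startswith("sub:") else c for c in df.columns]
        return df
    return counts.copy()


def frequency_table(
    counts: FeatureMatrix | pd.DataFrame,
    groups: Mapping[str, str],
    counting: str = "presence",
) -> pd.DataFrame:
    """Frequency statistics of every key in every group.

    ``counts`` holds per-compound match counts per key (rows indexed by
    compound id); ``groups`` maps every compound id to its group.  Returns a
    DataFrame indexed by key with columns ``f``, ``C`` and ``f_<g>``,
    ``C_<g>``, ``freq_<g>`` for each group ``g``.  A key absent from the
    whole dataset (``f = 0``) has frequency 0 in every group.
    """
    if counting not in ("presence", "occurrence"):
        raise ValueError(f"counting must be 'presence' or 'occurrence', got {counting!r}")
    df = _counts_frame(counts)
    df.index = df.index.astype(str)
    groups = {str(k): v for k, v in groups.items()}
    missing = set(df.index) - set(groups)
    if missing:
        raise ValueError(f"{len(missing)} compounds have no group assignment")
    membership = pd.Series({i: groups[i] for i in df.index})
    contrib = (df > 0).astype(float) if counting == "presence" else df.astype(float)

    C = float(len(df))
    f = contrib.sum(axis=0)
    out = pd.DataFrame({"f": f, "C": C})
    group_names = sorted(set(membership))
    for g in group_names:
        members = membership[membership == g].index
        if len(members) == 0:
            raise ValueError(f"group {g!r} is empty")
        C_x = float(len(members))
        f_x = contrib.loc[members].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(f > 0, (f_x * C) / (f * C_x), 0.0)
        out[f"f_{g}"] = f_x
        out[f"C_{g}"] = C_x
        out[f"freq_{g}"] = freq
    out.index.name = "key"
    return out


def substructure_frequency(
    counts: FeatureMatrix | pd.DataFrame,
    groups: Mapping[str, str],
    group_x: str,
    counting: str = "presence",
) -> pd.DataFrame:
    """Frequency rows for one group: key, f_x, C_x, f, C, freq_x."""
    table = frequency_table(counts, groups, counting)
    if f"freq_{group_x}" not in table.columns:
        raise ValueError(f"group {group_x!r} not present in the group assignment")
    return table[["f", "C", f"f_{group_x}", f"C_{group_x}", f"freq_{group_x}"]].rename(
        columns={f"f_{group_x}": "f_x", f"C_{group_x}": "C_x", f"freq_{group_x}": "freq_x"}
    )


def identify_active_substructures(
    table: pd.DataFrame,
    group_hi: str = "A1",
    group_lo: str = "C",
    freq_min: float = 1.2,
    ratio_min: float = 1.2,
) -> pd.DataFrame:
    """Flag active substructures and rank them.

    A key is active iff ``freq_hi > freq_min`` and ``freq_hi / freq_lo >
    ratio_min`` (``freq_lo = 0`` with ``freq_hi > freq_min`` counts as
    active, ratio +inf).  Returns the table with added ``ratio`` and
    ``active`` columns, sorted by ratio descending, then ``freq_hi``
    descending, then key name.
    """
    hi_col, lo_col = f"freq_{group_hi}", f"freq_{group_lo}"
    for col in (hi_col, lo_col):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing; run frequency_table over both groups")
    hi = table[hi_col].to_numpy(dtype=float)
    lo = table[lo_col].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, 0.0))
    out = table.copy()
    out["ratio"] = ratio
    out["active"] = (hi > freq_min) & (ratio > ratio_min)
    order = np.lexsort((out.index.astype(str), -hi, -np.nan_to_num(ratio, posinf=np.finfo(float).max)))
    return out.iloc[order]
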