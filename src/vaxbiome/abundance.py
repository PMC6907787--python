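"""Count-table filtering and transformation.

Implements the mock-community-derived per-OTU count cutoff, relative
abundance, taxonomic aggregation, the >1%-in-a-sample prevalence rule,
cumulative sum scaling (CSS) normalization, and the study-specific dropping
of the RB-only time points.

The mock cutoff follows the contamination-guard logic: the largest count any
OTU *not* expected in the mock community attains across the mock samples is
taken as the noise ceiling, and every count at or below it is zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ConfigError

__all__ = [
    "mock_based_cutoff",
    "apply_count_threshold",
    "relative_abundance",
    "aggregate_taxa",
    "prevalent_taxa",
    "css_normalize",
    "harmonize_timepoints",
    "NormalizedTable",
    "validate_count_table",
]


def validate_count_table(table: pd.DataFrame) -> None:
    """Check the CountTable invariants: unique ids, non-negative integers."""
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise DataError(f"duplicate sample id {dup!r}")
    if table.columns.duplicated().any():
        dup = table.columns[table.columns.duplicated()][0]
        raise DataError(f"duplicate OTU id {dup!r}")
    values = table.to_numpy()
    if (values < 0).any():
        raise DataError("count table contains negative entries")


def mock_based_cutoff(mock_counts: pd.DataFrame, expected_members: Iterable[str]) -> int:
    """Per-OTU count cutoff derived from mock-community samples.

    Returns the maximum count, over all mock samples, of any OTU that is not
    an expected mock member — i.e. the largest spurious count observed.
    Returns 0 when no non-member OTU has a nonzero count.
    """
    if mock_counts.empty:
        raise DataError("mock count table is empty; cutoff undefined")
    members = set(expected_members)
    non_member_cols = [c for c in mock_counts.columns if c not in members]
    if not non_member_cols:
        return 0
    return int(mock_counts[non_member_cols].to_numpy().max(initial=0))


def apply_count_threshold(table: pd.DataFrame, threshold: int) -> pd.DataFrame:
    """Zero every entry less than or equal to ``threshold``.

    The cutoff count itself is deemed noise (comparison is ``<=``).  OTU
    columns that become all-zero are retained so identifier alignment with
    the taxonomy never breaks; their ids are listed in
    ``result.attrs["all_zero_otus"]``.
    """
    if threshold < 0:
        raise ConfigError("threshold must be non-negative")
    out = table.where(table > threshold, 0)
    out.attrs["threshold"] = int(threshold)
    out.attrs["all_zero_otus"] = [c for c in out.columns if not (out[c] > 0).any()]
    return out


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Convert counts to per-sample proportions (rows sum to 1)."""
    totals = table.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise DataError(f"sample {zero.index[0]!r} has zero total count")
    return table.div(totals, axis=0)


def aggregate_taxa(table: pd.DataFrame, taxonomy: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Sum OTU columns sharing the same label at ``rank``.

    Column order of the result is label-sorted; per-sample totals are
    conserved exactly (integer arithmetic).
    """
    if rank not in taxonomy.columns:
        raise ConfigError(f"unknown rank {rank!r}; expected one of {list(taxonomy.columns)}")
    missing = [c for c in table.columns if c not in taxonomy.index]
    if missing:
        raise DataError(f"OTUs missing from taxonomy: {missing}")
    labels = taxonomy.loc[table.columns, rank]
    out = table.T.groupby(labels.values).sum().T
    return out.reindex(sorted(out.columns), axis=1)


def prevalent_taxa(relabund: pd.DataFrame, min_fraction: float = 0.01) -> list[str]:
    """Taxa whose relative abundance exceeds ``min_fraction`` in >= 1 sample.

    The comparison is strict (a taxon at exactly the threshold everywhere is
    excluded); taxa are returned in the table's column order.
    """
    if not (0 <= min_fraction < 1):
        raise ConfigError("min_fraction must lie in [0, 1)")
    mask = (relabund > min_fraction).any(axis=0)
    return [c for c in relabund.columns if mask[c]]


@dataclass
class NormalizedTable:
    """CSS-normalized table with the per-sample scale factors used."""

    data: pd.DataFrame
    scale_factors: pd.Series
    quantile: float


def css_normalize(table: pd.DataFrame, quantile: float = 0.5) -> NormalizedTable:
    """Cumulative sum scaling.

    For sample j, the scale factor s_j is the sum of that sample's counts
    that are <= the ``quantile``-th quantile of its *nonzero* counts; entries
    are divided by s_j and rescaled by 1000.  Identical compositions at
    different depths normalize to identical rows.
    """
    if not (0 < quantile <= 1):
        raise ConfigError("quantile must lie in (0, 1]")
    factors = {}
    rows = {}
    for sid, row in table.iterrows():
        values = row.to_numpy(dtype=float)
        nonzero = values[values > 0]
        if nonzero.size == 0:
            raise DataError(f"sample {sid!r} is empty; CSS scale factor undefined")
        q = np.quantile(nonzero, quantile)
        s_j = values[values <= q].sum()
        if s_j <= 0:
            raise DataError(f"sample {sid!r} has zero CSS scale factor")
        factors[sid] = float(s_j)
        rows[sid] = values / s_j * 1000.0
    data = pd.DataFrame.from_dict(rows, orient="index", columns=table.columns)
    data.index.name = table.index.name
    return NormalizedTable(data=data, scale_factors=pd.Series(factors), quantile=quantile)


def harmonize_timepoints(
    samples: pd.DataFrame,
    treatment: str = "RB",
    drop_weeks: Sequence[int] = (-1, 12),
) -> tuple[pd.DataFrame, int]:
    """Drop the RB-only weeks so all treatments share the same time grid.

    Returns the filtered table and the number of rows dropped.  Idempotent.
    """
    if "week" not in samples.columns:
        raise DataError("sample table lacks a 'week' column")
    mask = (samples["treatment"] == treatment) & samples["week"].isin(list(drop_weeks))
    return samples.loc[~mask].copy(), int(mask.sum())
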