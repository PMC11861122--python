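"""Tabulation helpers shared by the pipeline outputs and report scripts.

All percentage columns in the stage outputs are produced by these
helpers, so count tables (including externally supplied ones) can be fed
through the same arithmetic.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd


def percent(numerator: float, denominator: float,
            ndigits: int = 2) -> float:
    """100 * numerator / denominator, rounded."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, ndigits)


def share_of_counts(counts: Mapping[str, int],
                    numerator_bins: Iterable[str],
                    denominator_bins: Iterable[str] | None = None,
                    ndigits: int = 2) -> float:
    """Percentage of the selected bins within a count table.

    ``denominator_bins`` defaults to all bins.  Used both for pipeline
    percentage columns and for re-deriving shares from published count
    tables.
    """
    numer = sum(counts[b] for b in numerator_bins)
    bins = list(denominator_bins) if denominator_bins is not None \
        else list(counts)
    denom = sum(counts[b] for b in bins)
    return percent(numer, denom, ndigits)


def complement_share(counts: Mapping[str, int], zero_bin: str,
                     total: int, ndigits: int = 2) -> float:
    """100 * (total - counts[zero_bin]) / total."""
    return percent(total - counts[zero_bin], total, ndigits)


def add_percent_column(table: pd.DataFrame, n_col: str = "n",
                       total: float | None = None,
                       ndigits: int = 2) -> pd.DataFrame:
    """Return a copy of ``table`` with a percent column over ``n_col``."""
    out = table.copy()
    denom = total if total is not None else out[n_col].sum()
    out["percent"] = [percent(v, denom, ndigits) for v in out[n_col]]
    return out
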