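"""Two-database protein-set comparison.

A query protein from database A "matches" database B when both carry a
conserved-domain annotation and at least one hit passes the E-value and
bit-score gates (E <= cutoff, bit >= threshold; boundaries inclusive).
The matched-set size is non-increasing in the bit threshold. Shared GO
percentages are reported per category as 100 * shared / total, rounded
half-up to one decimal.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import ConfigError, InputError


@dataclass
class CompareConfig:
    e_cutoff: float = 1e-5
    bit_thresholds: tuple[float, ...] = (90.0, 120.0, 200.0)
    sharing_threshold: float = 120.0

    def __post_init__(self):
        if any(t <= 0 for t in self.bit_thresholds):
            raise ConfigError("bit thresholds must be positive")
        if tuple(sorted(self.bit_thresholds)) != tuple(self.bit_thresholds):
            raise ConfigError("bit thresholds must be sorted ascending")
        if self.e_cutoff <= 0:
            raise ConfigError("e_cutoff must be positive")


def filter_matches(hits: pd.DataFrame, annotated_a: Iterable[str],
                   annotated_b: Iterable[str], e_cutoff: float,
                   bit_threshold: float) -> set[str]:
    """A-proteins matched to B under the E/bit gates, restricted to
    domain-annotated sequences on both sides."""
    annotated_a = set(annotated_a)
    annotated_b = set(annotated_b)
    ok = hits[
        hits["qseqid"].isin(annotated_a)
        & hits["sseqid"].isin(annotated_b)
        & (hits["evalue"] <= e_cutoff)
        & (hits["bitscore"] >= bit_threshold)
    ]
    return set(ok["qseqid"].unique())


def match_counts(hits: pd.DataFrame, annotated_a, annotated_b,
                 config: Optional[CompareConfig] = None) -> pd.DataFrame:
    """Matched-protein counts at each configured bit threshold."""
    config = config or CompareConfig()
    rows = [(config.e_cutoff, t,
             len(filter_matches(hits, annotated_a, annotated_b,
                                config.e_cutoff, t)))
            for t in config.bit_thresholds]
    return pd.DataFrame(rows, columns=["e_cutoff", "bit_threshold",
                                       "matched"])


def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def shared_percentage(total: int, shared: int) -> Optional[float]:
    """100 * shared / total, half-up to one decimal; None when total=0."""
    if shared > total:
        raise InputError(f"shared ({shared}) exceeds total ({total})")
    if total == 0:
        return None
    pct = (Decimal(shared) * 100 / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(pct)


def shared_go_table(totals: Mapping[str, int],
                    shared: Mapping[str, int]) -> pd.DataFrame:
    """Per-category shared-annotation percentages.

    ``totals`` gives the A-database product count per category;
    ``shared`` the count also matched in B. Categories with total 0
    report a not-applicable (NaN) percentage.
    """
    rows = []
    for cat in totals:
        t = int(totals[cat])
        s = int(shared.get(cat, 0))
        pct = shared_percentage(t, s)
        rows.append((cat, t, s, float("nan") if pct is None else pct))
    return pd.DataFrame(rows, columns=["category", "total", "shared",
                                       "shared_percentage"])
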