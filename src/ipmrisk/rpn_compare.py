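"""Classical risk-priority-number (RPN) computation and its pathologies.

The RPN multiplies ordinal scores (severity x occurrence x detectability,
or just S x O when detectability is not assessed).  Because products of
small integers repeat and cluster, most of the nominal 1..levels^3 scale
is unattainable, and distinct score profiles collide on the same RPN.
This module quantifies both effects and compares RPN rankings against the
simulation-based CQA-reduction ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

__all__ = ["rpn", "RPNScaleReport", "scale_coverage", "compare_rankings",
           "count_inversions", "ambiguous_rpn_groups"]


def rpn(severity: int, occurrence: int, detectability: int | None = None) -> int:
    """Product of the provided ordinal scores (two-factor form when D is absent)."""
    factors = [severity, occurrence] + ([] if detectability is None else [detectability])
    for f in factors:
        if f < 1:
            raise ValueError(f"scores must be >= 1, got {factors}")
    out = 1
    for f in factors:
        out *= int(f)
    return out


@dataclass(frozen=True)
class RPNScaleReport:
    """Coverage of the nominal RPN scale 1..levels^3 by attainable products."""

    levels: int
    n_cells: int
    distinct_values: int
    pct_empty: float


def scale_coverage(levels: int) -> RPNScaleReport:
    """Enumerate all (S, O, D) triples and report how empty the RPN scale is.

    pct_empty is taken over the nominal scale 1..levels^3 (e.g. 1..1000
    for ten levels), not over the attained range.
    """
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    products = {s * o * d for s, o, d in product(range(1, levels + 1), repeat=3)}
    n_cells = levels ** 3
    distinct = len(products)
    return RPNScaleReport(levels=levels, n_cells=n_cells, distinct_values=distinct,
                          pct_empty=100.0 * (n_cells - distinct) / n_cells)


def compare_rankings(table: pd.DataFrame,
                     reduction_col: str = "mean_cqa_reduction_pct") -> pd.DataFrame:
    """Side-by-side RPN vs simulated-reduction ranking per PP.

    A PP is flagged ``inversion`` when at least one other PP orders
    oppositely under the two metrics (strictly higher RPN but strictly
    lower reduction, or vice versa).  ``rpn_ambiguous`` marks PPs sharing
    their RPN value with a PP of different reduction — the equal-RPN,
    unequal-impact case.
    """
    for col in ("rpn", reduction_col):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from criticality table")
    out = table[[c for c in ("uo", "pp", "severity", "occurrence") if c in table.columns]].copy()
    r = table["rpn"].to_numpy(dtype=float)
    q = table[reduction_col].to_numpy(dtype=float)
    out["rpn"] = table["rpn"].to_numpy()
    out["reduction"] = q
    out["rpn_rank"] = table["rpn"].rank(method="min").astype(int)
    out["reduction_rank"] = table[reduction_col].rank(method="min").astype(int)
    dr = r[:, None] - r[None, :]
    dq = q[:, None] - q[None, :]
    discordant = (dr * dq) < 0
    out["inversion"] = discordant.any(axis=1)
    same_rpn = (dr == 0) & ~np.eye(len(r), dtype=bool)
    out["rpn_ambiguous"] = (same_rpn & (dq != 0)).any(axis=1)
    return out


def count_inversions(table: pd.DataFrame,
                     reduction_col: str = "mean_cqa_reduction_pct") -> int:
    """Number of PP pairs ordered oppositely by RPN and by reduction."""
    r = table["rpn"].to_numpy(dtype=float)
    q = table[reduction_col].to_numpy(dtype=float)
    dr = r[:, None] - r[None, :]
    dq = q[:, None] - q[None, :]
    return int(((dr * dq) < 0).sum() // 2)


def ambiguous_rpn_groups(table: pd.DataFrame,
                         reduction_col: str = "mean_cqa_reduction_pct") -> pd.DataFrame:
    """RPN values shared by PPs with distinct reductions, one row per group."""
    rows = []
    for value, grp in table.groupby("rpn"):
        reds = grp[reduction_col].to_numpy(dtype=float)
        if len(grp) > 1 and len(np.unique(reds)) > 1:
            rows.append({"rpn": value, "n_pps": len(grp),
                         "min_reduction": float(reds.min()),
                         "max_reduction": float(reds.max()),
                         "pps": ", ".join(grp["pp"].astype(str))})
    return pd.DataFrame(rows, columns=["rpn", "n_pps", "min_reduction",
                                       "max_reduction", "pps"])
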