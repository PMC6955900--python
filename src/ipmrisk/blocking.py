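"""Detectability-based blocking and escalation of the criticality ranking.

Detectability does not enter the simulation; it refines the final ranking.
The reduction-ranked PPs are partitioned into 4 blocks (fewer than 28 PPs)
or 6 blocks (28 or more), as equal as possible with the larger blocks
first, block 1 holding the highest-reduction PPs.  Within each block the
PP with the worst (highest) detectability score is the block's most
critical; when that PP is not also the block's top-reduction PP, the
detectability signal contradicts the reduction ranking and the whole
block is escalated to critical.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["BlockAssignment", "block_sizes", "assign_blocks", "escalate",
           "as_block_assignments"]


@dataclass(frozen=True)
class BlockAssignment:
    """One contiguous block of the reduction-ranked PP list."""

    block_id: int
    members: tuple[str, ...]          # pp names ordered by detectability desc
    most_critical: str                # top-detectability member
    block_critical: bool              # whole block escalated?


def block_sizes(n: int) -> list[int]:
    """Balanced partition sizes: 4 blocks below 28 PPs, 6 otherwise.

    Remainder front-loaded, so 23 -> [6, 6, 6, 5] and 28 -> [5, 5, 5, 5, 4, 4].
    """
    if n < 1:
        raise ValueError("cannot block an empty PP list")
    n_blocks = min(4 if n < 28 else 6, n)  # never emit empty blocks
    base, rem = divmod(n, n_blocks)
    return [base + 1] * rem + [base] * (n_blocks - rem)


def assign_blocks(table: pd.DataFrame,
                  reduction_col: str = "mean_cqa_reduction_pct") -> pd.DataFrame:
    """Add ``block_id`` (1 = highest-reduction block) to a criticality table."""
    if table.empty:
        raise ValueError("cannot block an empty PP list")
    if "detectability" not in table.columns or table["detectability"].isna().any():
        raise ValueError(
            "detectability scores are required for blocking; "
            "run the ranking without the blocking step instead")
    out = table.sort_values(reduction_col, ascending=False,
                            kind="mergesort").reset_index(drop=True)
    ids = []
    for bid, size in enumerate(block_sizes(len(out)), start=1):
        ids.extend([bid] * size)
    out["block_id"] = pd.array(ids, dtype="Int64")
    return out


def escalate(table: pd.DataFrame,
             reduction_col: str = "mean_cqa_reduction_pct") -> tuple[pd.DataFrame, list[str]]:
    """Apply the within-block detectability escalation rule.

    Returns the updated table plus human-readable warnings for every
    escalated block (the stopping condition of the escalation rule is
    judgement-laden, so escalations are surfaced rather than silent).
    Existing ``is_critical`` flags are never cleared.
    """
    if "block_id" not in table.columns or table["block_id"].isna().any():
        raise ValueError("assign_blocks must run before escalate")
    out = table.copy()
    if "is_critical" not in out.columns:
        out["is_critical"] = False
    out["is_block_most_critical"] = False
    out["block_escalated"] = False
    warnings: list[str] = []
    for bid, grp in out.groupby("block_id", sort=True):
        # worst detectability first; ties broken by reduction
        ordered = grp.sort_values(["detectability", reduction_col],
                                  ascending=[False, False], kind="mergesort")
        top_d_idx = ordered.index[0]
        top_red_idx = grp[reduction_col].idxmax()
        out.loc[top_d_idx, "is_block_most_critical"] = True
        if top_d_idx != top_red_idx:
            out.loc[grp.index, "is_critical"] = True
            out.loc[grp.index, "block_escalated"] = True
            warnings.append(
                f"block {bid}: hardest-to-detect PP "
                f"{out.loc[top_d_idx, 'pp']!r} is not its top-reduction PP "
                f"{out.loc[top_red_idx, 'pp']!r}; whole block escalated to critical")
    return out, warnings


def as_block_assignments(table: pd.DataFrame,
                         reduction_col: str = "mean_cqa_reduction_pct") -> list[BlockAssignment]:
    """View an escalated table as structured block assignments."""
    if "is_block_most_critical" not in table.columns:
        raise ValueError("escalate must run before building block assignments")
    blocks = []
    for bid, grp in table.groupby("block_id", sort=True):
        ordered = grp.sort_values(["detectability", reduction_col],
                                  ascending=[False, False], kind="mergesort")
        most = ordered.iloc[0]["pp"]
        blocks.append(BlockAssignment(
            block_id=int(bid),
            members=tuple(ordered["pp"]),
            most_critical=str(most),
            block_critical=bool(grp["block_escalated"].any()),
        ))
    return blocks
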