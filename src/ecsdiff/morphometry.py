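"""Microglia ramification ("dendritic density") index.

Quantifies how densely a cell's processes fill space from a pre-extracted
skeleton summary:

    index = (sum of terminal branch orders + number of terminals)
            * (total process length / number of primary processes)

Branch order starts at 1 for a primary process leaving the soma and
increases by one at each branch point.  The index grows with arborisation
(more, higher-order terminals) and with total length, and is normalised
by the number of primary processes.  Operates on summaries, not images;
segmentation and 3-D reconstruction happen upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["NeuriteSkeletonSummary", "ramification_index", "read_skeletons_csv", "index_table"]


@dataclass
class NeuriteSkeletonSummary:
    """Per-cell skeleton summary: terminals, orders, length, primaries."""

    terminal_orders: Sequence[int]
    n_terminals: int
    total_length: float  # um
    n_primary: int
    cell_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.terminal_orders = [int(o) for o in self.terminal_orders]
        if any(o < 1 for o in self.terminal_orders):
            raise ValueError("terminal orders must be positive integers")
        if self.n_terminals != len(self.terminal_orders):
            raise ValueError("n_terminals must equal len(terminal_orders)")
        if self.n_primary < 1:
            raise ValueError("n_primary must be >= 1")
        if self.total_length <= 0:
            raise ValueError("total_length must be > 0")


def ramification_index(s: NeuriteSkeletonSummary) -> float:
    """(sum of terminal orders + n terminals) * (total length / n primary)."""
    return (sum(s.terminal_orders) + s.n_terminals) * (s.total_length / s.n_primary)


def read_skeletons_csv(path_or_buf) -> list[NeuriteSkeletonSummary]:
    """Read per-cell summaries from CSV.

    Expected columns: cell_id, group, terminal_orders (';'-separated
    integers), total_length_um, n_primary.
    """
    df = pd.read_csv(path_or_buf)
    out = []
    for _, row in df.iterrows():
        orders = [int(x) for x in str(row["terminal_orders"]).split(";") if x != ""]
        out.append(
            NeuriteSkeletonSummary(
                terminal_orders=orders,
                n_terminals=len(orders),
                total_length=float(row["total_length_um"]),
                n_primary=int(row["n_primary"]),
                cell_id=str(row.get("cell_id", "")),
                group=str(row.get("group", "")),
            )
        )
    return out


def index_table(summaries: Sequence[NeuriteSkeletonSummary]) -> pd.DataFrame:
    """Index per cell plus a per-group mean +/- SE summary attribute."""
    df = pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in summaries],
            "group": [s.group for s in summaries],
            "ramification_index": [ramification_index(s) for s in summaries],
        }
    )
    return df
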