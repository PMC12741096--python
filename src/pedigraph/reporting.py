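"""Aggregate relation labels across probands and render the summary grid.

The grid is a classical consanguinity chart indexed by generations up
(rows) and generations down (columns); each cell shows the relationship
code, the total count across probands and the mean per proband. Members
labelled "Unrelated" or "Distant" appear in the tabular summary but not
in the figure, which shows named relations only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import pandas as pd

from . import relations as rel
from .relations import FULL, HALF, MAX_DEGREE, MAX_UP, classify_pair


def standard_codes() -> list[str]:
    """Every labelable code within the bounds (ascent <= 6, degree <= 9),
    full and half variants included; "Self" excluded."""
    codes: dict[str, None] = {}
    for up in range(MAX_UP + 1):
        for down in range(MAX_UP + 1):
            if up == 0 and down == 0:
                continue
            variants = [FULL, HALF] if (up >= 1 and down >= 1) else ["not_applicable"]
            for fullness in variants:
                label = classify_pair(up, down, fullness)
                if label.degree <= MAX_DEGREE:
                    codes.setdefault(label.code)
    return list(codes)


@dataclass
class RelationSummary:
    """Totals and per-proband means of each relationship code."""

    n_probands: int
    per_code: dict[str, tuple[int, float]] = field(default_factory=dict)
    n_unrelated: int = 0
    n_distant: int = 0

    def total(self, code: str) -> int:
        return self.per_code.get(code, (0, 0.0))[0]

    def mean(self, code: str) -> float:
        return self.per_code.get(code, (0, 0.0))[1]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (code, total, mean) for code, (total, mean) in self.per_code.items()
        ]
        rows.append((rel.UNRELATED_CODE, self.n_unrelated,
                     self.n_unrelated / self.n_probands))
        rows.append((rel.DISTANT_CODE, self.n_distant,
                     self.n_distant / self.n_probands))
        return pd.DataFrame(rows, columns=["code", "total", "mean_per_proband"])

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df["mean_per_proband"] = df["mean_per_proband"].round(3)
        df.to_csv(path, sep="\t", index=False)


def relation_summary(relations: pd.DataFrame, n_probands: int) -> RelationSummary:
    """Count each relationship code over a :func:`~pedigraph.relations.get_relations`
    table covering ``n_probands`` probands.

    "Self" rows are excluded; every standard code is reported even when
    its total is zero, so sparse families still yield a full grid.
    """
    if n_probands < 1:
        raise ValueError(f"n_probands must be >= 1, got {n_probands}")
    counts = relations["code"].value_counts().to_dict()
    counts.pop(rel.SELF_CODE, None)
    n_unrelated = counts.pop(rel.UNRELATED_CODE, 0)
    n_distant = counts.pop(rel.DISTANT_CODE, 0)
    per_code = {
        code: (counts.get(code, 0), counts.get(code, 0) / n_probands)
        for code in standard_codes()
    }
    for code, total in counts.items():  # observed codes outside the grid
        if code not in per_code:
            per_code[code] = (total, total / n_probands)
    return RelationSummary(int(n_probands), per_code, int(n_unrelated), int(n_distant))


def _grid_positions() -> dict[str, tuple[int, int, str]]:
    """code -> (up, down, fullness) for grid placement."""
    positions = {}
    for up in range(MAX_UP + 1):
        for down in range(MAX_UP + 1):
            if up == 0 and down == 0:
                continue
            variants = [FULL, HALF] if (up >= 1 and down >= 1) else ["not_applicable"]
            for fullness in variants:
                label = classify_pair(up, down, fullness)
                if label.degree <= MAX_DEGREE and label.code not in positions:
                    positions[label.code] = (up, down, fullness)
    return positions


def relation_grid_figure(summary: RelationSummary, path: str | Path) -> Path:
    """Render the (up x down) relation grid with one "CODE total (mean)"
    entry per code; full codes in the upper half of a cell, half codes in
    the lower. PNG and SVG are supported (by file extension); SVG output
    is byte-deterministic for a fixed summary."""
    path = Path(path)
    positions = _grid_positions()

    fig, ax = plt.subplots(figsize=(12, 9))
    ax.set_xlim(-0.5, MAX_UP + 0.5)
    ax.set_ylim(MAX_UP + 0.5, -0.5)
    ax.set_xlabel("generations down to relative")
    ax.set_ylabel("generations up to common ancestor")
    ax.set_xticks(range(MAX_UP + 1))
    ax.set_yticks(range(MAX_UP + 1))
    ax.set_title(f"relations per proband (n={summary.n_probands})")

    cells: set[tuple[int, int]] = {(0, 0)}
    ax.text(0, 0, "Self", ha="center", va="center", fontsize=9, weight="bold")
    for code, (up, down, fullness) in positions.items():
        cells.add((up, down))
        text = f"{code} {summary.total(code)} ({summary.mean(code):.3f})"
        offset = -0.18 if fullness != HALF else 0.18
        if fullness == "not_applicable":
            offset = 0.0
        ax.text(down, up + offset, text, ha="center", va="center", fontsize=7)
    for up, down in cells:
        ax.add_patch(
            plt.Rectangle(
                (down - 0.48, up - 0.48), 0.96, 0.96,
                fill=False, edgecolor="0.6", linewidth=0.8,
            )
        )
    fig.tight_layout()
    with matplotlib.rc_context({"svg.hashsalt": "pedigraph"}):
        fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
    plt.close(fig)
    return path
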