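"""Pipeline assembly: per-segment reconstruction, reports and summaries.

Ties the stages together the way the study pipeline runs them: encode or
load the character matrix, reconstruct every cluster-bearing segment,
call states at the probability threshold, list insertion/deletion
events, run the correlated-evolution screen, and classify breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ctmc
from .ancestral import AncestralTable, EventCall, FittedARD, call_events, classify_states, fit_ard, marginal_probs
from .phylo_core import Tree

__all__ = [
    "RunConfig",
    "SegmentReconstruction",
    "reconstruct_segments",
    "event_summary",
    "events_to_frame",
    "matrix_tip_data",
]


@dataclass
class RunConfig:
    """Run parameters shared by the pipeline commands."""

    tree: str | None = None
    matrix: str | None = None
    annotations: str | None = None
    breakpoints: str | None = None
    threshold: float = 0.75
    alpha: float = 0.05
    seed: int = 0
    out: str = "norevo_out"
    n_restarts: int = 5

    def __post_init__(self):
        if not 0.5 < self.threshold <= 1.0:
            raise ValueError(f"threshold must be in (0.5, 1], got {self.threshold}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat ``key = value`` config file; file entries take precedence."""
        values = dict(overrides)
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
        for key in ("threshold", "alpha"):
            if key in values:
                values[key] = float(values[key])
        for key in ("seed", "n_restarts"):
            if key in values:
                values[key] = int(values[key])
        return cls(**values)


@dataclass
class SegmentReconstruction:
    segment: str
    fitted: FittedARD
    table: AncestralTable  # with threshold calls
    events: list[EventCall] = field(default_factory=list)


def matrix_tip_data(matrix: pd.DataFrame, segment: str) -> dict[str, np.ndarray]:
    """One segment column of the character matrix as tip observation vectors."""
    return {taxon: ctmc.tip_vector(v if str(v) == "?" else int(v), 3) for taxon, v in matrix[segment].items()}


def reconstruct_segments(
    tree: Tree,
    matrix: pd.DataFrame,
    *,
    threshold: float = 0.75,
    seed: int = 0,
    n_restarts: int = 5,
) -> dict[str, SegmentReconstruction]:
    """Fit, reconstruct, call and list events for every cluster-bearing segment.

    Segments on which no taxon ever carries a cluster are skipped (their
    ancestral state is trivially absent and carries no information).
    Deterministic given ``seed``.
    """
    out: dict[str, SegmentReconstruction] = {}
    for i, seg in enumerate(matrix.columns):
        observed = {str(v) for v in matrix[seg]}
        if not observed & {"1", "2"}:
            continue
        tips = matrix_tip_data(matrix, seg)
        fitted = fit_ard(tree, tips, seed=seed + 7 * i, n_restarts=n_restarts)
        table = marginal_probs(tree, tips, fitted, segment=seg)
        called = classify_states(table, threshold)
        events = call_events(tree, called)
        out[seg] = SegmentReconstruction(seg, fitted, called, events)
    return out


def events_to_frame(recons: dict[str, SegmentReconstruction]) -> pd.DataFrame:
    rows = []
    for rec in recons.values():
        for ev in rec.events:
            rows.append(
                {
                    "segment": rec.segment,
                    "type": ev.type,
                    "depth": "terminal" if ev.terminal else "deep",
                    "node": ev.node,
                    "clade": "|".join(rec.table.tree.clade_tips(ev.node)),
                    "probability_pct": round(ev.probability_pct, 1),
                }
            )
    return pd.DataFrame(rows, columns=["segment", "type", "depth", "node", "clade", "probability_pct"])


def event_summary(recons: dict[str, SegmentReconstruction]) -> dict[str, int]:
    """Counts of insertions/deletions split into deep-node vs terminal-branch."""
    counts = {
        "deep_insertions": 0,
        "deep_deletions": 0,
        "terminal_insertions": 0,
        "terminal_deletions": 0,
    }
    for rec in recons.values():
        for ev in rec.events:
            key = ("terminal_" if ev.terminal else "deep_") + (
                "insertions" if ev.type == "insertion" else "deletions"
            )
            counts[key] += 1
    return counts
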