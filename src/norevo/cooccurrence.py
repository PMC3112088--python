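"""Breakpoint classification by rDNA-cluster and centromere context.

Each evolutionary breakpoint (a fission, fusion, translocation or
inversion site on the chromosomal phylogeny) is placed on a branch of
the reference tree and on one of the 30 orthologous segments. It is
classified by whether an rDNA cluster — taken from the called ancestral
reconstruction of that segment at the branch's parent node, i.e. the
state when the rearrangement occurred — and a centromere were present:

* ``undetermined``   — the cluster call at the branch is unknown;
* ``neither``        — neither a cluster nor a centromere was present;
* ``cluster_and_centromere`` — both present (the break flanks the
  cluster: at its distal end, or between centromere and cluster);
* ``other``          — the remaining combinations (one of the two
  structures present).

The headline statistic is the percentage of determinable breakpoints
that occurred on either side of a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ancestral import PRESENT, AncestralTable
from .characters import SEGMENTS
from .phylo_core import Tree

__all__ = [
    "BreakpointRecord",
    "BreakpointClassification",
    "CooccurrenceSummary",
    "classify_breakpoints",
    "summarize",
    "load_breakpoints",
]

REARRANGEMENT_CLASSES = ("fission", "fusion", "translocation", "inversion")
SUB_POSITIONS = ("distal_end_of_cluster", "between_centromere_and_cluster")
CENTROMERE_FATES = ("lost", "lost_then_reacquired", "retained")


@dataclass
class BreakpointRecord:
    """One breakpoint, placed on a segment and a branch of the tree.

    The branch is identified by its child clade (sorted tip labels).
    ``centromere_present`` records whether a centromere sat on the
    segment when the rearrangement occurred, and ``sub_position`` /
    ``centromere_fate`` the scenario details where the break flanked a
    cluster; these come from the transcribed rearrangement scenarios,
    not from the reconstruction.
    """

    breakpoint_id: str
    segment: str
    rearrangement: str
    child_clade: tuple[str, ...]
    centromere_present: bool
    sub_position: str | None = None
    centromere_fate: str | None = None

    def __post_init__(self):
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment label: {self.segment!r}")
        if self.rearrangement not in REARRANGEMENT_CLASSES:
            raise ValueError(f"unknown rearrangement class: {self.rearrangement!r}")


@dataclass
class BreakpointClassification:
    breakpoint_id: str
    segment: str
    category: str  # undetermined | neither | cluster_and_centromere | other
    cluster_call: str
    centromere_present: bool
    sub_position: str | None = None
    centromere_fate: str | None = None


@dataclass
class CooccurrenceSummary:
    total: int
    n_undetermined: int
    n_neither: int
    n_both: int
    n_other: int
    percent_flanking: float | None  # 100 * n_both / (total - n_undetermined)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "total": self.total,
                    "undetermined": self.n_undetermined,
                    "neither": self.n_neither,
                    "cluster_and_centromere": self.n_both,
                    "other": self.n_other,
                    "percent_flanking": self.percent_flanking,
                }
            ]
        )


def classify_breakpoints(
    breakpoints: list[BreakpointRecord],
    tables: dict[str, AncestralTable],
    tree: Tree,
) -> list[BreakpointClassification]:
    """Classify each breakpoint against the called ancestral tables.

    ``tables`` maps segment label -> called AncestralTable for that
    segment. The cluster state at a breakpoint is the call at the parent
    node of the breakpoint's branch (the state in place when the
    rearrangement happened).
    """
    out = []
    for bp in breakpoints:
        if bp.segment not in tables:
            raise KeyError(f"no ancestral table for segment {bp.segment!r}")
        table = tables[bp.segment]
        if table.calls is None:
            raise ValueError(f"ancestral table for {bp.segment} has no calls")
        child = tree.node_by_clade(bp.child_clade)
        parent = tree.parent[child]
        if parent < 0:
            raise ValueError(f"breakpoint {bp.breakpoint_id} placed above the root")
        call = table.calls[parent]
        cluster = None if call == "unknown" else (call in PRESENT)
        if cluster is None:
            category = "undetermined"
        elif cluster and bp.centromere_present:
            category = "cluster_and_centromere"
        elif not cluster and not bp.centromere_present:
            category = "neither"
        else:
            category = "other"
        out.append(
            BreakpointClassification(
                breakpoint_id=bp.breakpoint_id,
                segment=bp.segment,
                category=category,
                cluster_call=call,
                centromere_present=bp.centromere_present,
                sub_position=bp.sub_position if category == "cluster_and_centromere" else None,
                centromere_fate=bp.centromere_fate if category == "cluster_and_centromere" else None,
            )
        )
    return out


def summarize(classifications: list[BreakpointClassification]) -> CooccurrenceSummary:
    """Category counts and the flanking percentage.

    ``percent_flanking`` discounts the undetermined breakpoints from the
    denominator; it is ``None`` when no breakpoint is determinable.
    """
    total = len(classifications)
    counts = {"undetermined": 0, "neither": 0, "cluster_and_centromere": 0, "other": 0}
    for c in classifications:
        counts[c.category] += 1
    determined = total - counts["undetermined"]
    percent = 100.0 * counts["cluster_and_centromere"] / determined if determined else None
    return CooccurrenceSummary(
        total=total,
        n_undetermined=counts["undetermined"],
        n_neither=counts["neither"],
        n_both=counts["cluster_and_centromere"],
        n_other=counts["other"],
        percent_flanking=percent,
    )


def load_breakpoints(path) -> list[BreakpointRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    out = []
    for _, r in df.iterrows():
        out.append(
            BreakpointRecord(
                breakpoint_id=r["breakpoint_id"],
                segment=r["segment"],
                rearrangement=r["rearrangement"],
                child_clade=tuple(sorted(r["child_clade"].split("|"))),
                centromere_present=r["centromere_present"] == "1",
                sub_position=r["sub_position"] or None,
                centromere_fate=r["centromere_fate"] or None,
            )
        )
    return out
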