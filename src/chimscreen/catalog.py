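"""Classification of chimera calls and the specificity / MM filters.

Location categories: ``inter-chromosomal``, ``intra-chromosomal``,
``read-through``. Read-through requires same chromosome, same strand, the
3' partner downstream of the 5' partner in the shared transcription
direction, and an intergenic gap at most ``readthrough_gap`` bases.

Junction-site categories combine one letter per side: E when the breakpoint
coincides with the relevant exon boundary (donor edge for the 5' side,
acceptor edge for the 3' side, strand-aware), M otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .models import (
    BackgroundPanel,
    ChimeraCall,
    GeneModel,
    JUNCTION_CATEGORIES,
    LOCATION_CATEGORIES,
    ValidationError,
)

DEFAULT_READTHROUGH_GAP = 50_000
DEFAULT_EDGE_TOLERANCE = 0


@dataclass
class ClassifiedCall:
    """A call together with its two classification labels and flags."""

    call: ChimeraCall
    location: Optional[str] = None
    junction_site: Optional[str] = None
    flags: list[str] = field(default_factory=list)

    @property
    def call_id(self) -> str:
        return self.call.call_id


@dataclass
class FilterReport:
    """Audit of one filtering step: every removed id carries one reason."""

    n_input: int
    n_removed_panel: int = 0
    n_removed_mm: int = 0
    removed: list[tuple[str, str]] = field(default_factory=list)  # (call_id, reason)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed_panel - self.n_removed_mm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["call_id", "reason"])


def _gap_in_transcription_order(gene5: GeneModel, gene3: GeneModel) -> Optional[int]:
    """Signed intergenic gap (3' gene start minus 5' gene end, transcription
    orientation); None when the 3' gene is not strictly downstream."""
    if gene5.strand == "+":
        if gene3.start < gene5.end:
            return None
        return gene3.start - gene5.end
    if gene3.end > gene5.start:
        return None
    return gene5.start - gene3.end


def classify_location(
    call: ChimeraCall,
    annotation: dict[str, GeneModel],
    readthrough_gap: int = DEFAULT_READTHROUGH_GAP,
) -> str:
    """Assign exactly one location category to a call."""
    gene5 = annotation.get(call.gene5)
    gene3 = annotation.get(call.gene3)
    if gene5 is not None and gene5.chrom != call.chrom5:
        raise ValidationError(
            f"call {call.call_id}: chr {call.chrom5} contradicts annotation ({gene5.chrom}) for {call.gene5}"
        )
    if gene3 is not None and gene3.chrom != call.chrom3:
        raise ValidationError(
            f"call {call.call_id}: chr {call.chrom3} contradicts annotation ({gene3.chrom}) for {call.gene3}"
        )
    if call.chrom5 != call.chrom3:
        return "inter-chromosomal"
    if gene5 is None or gene3 is None:
        # coordinates only: same chromosome, gene extents unknown
        return "intra-chromosomal"
    if call.strand5 == call.strand3 == gene5.strand == gene3.strand:
        gap = _gap_in_transcription_order(gene5, gene3)
        if gap is not None and gap <= readthrough_gap:
            return "read-through"
    return "intra-chromosomal"


def _donor_edges(gene: GeneModel) -> list[int]:
    """Transcription-3' boundary (last transcribed base) of each exon."""
    if gene.strand == "+":
        return [end - 1 for _, end in gene.exons]
    return [start for start, _ in gene.exons]


def _acceptor_edges(gene: GeneModel) -> list[int]:
    """Transcription-5' boundary (first transcribed base) of each exon."""
    if gene.strand == "+":
        return [start for start, _ in gene.exons]
    return [end - 1 for _, end in gene.exons]


def classify_junction_site(
    call: ChimeraCall,
    annotation: dict[str, GeneModel],
    edge_tolerance: int = DEFAULT_EDGE_TOLERANCE,
) -> tuple[str, list[str]]:
    """Classify the junction as EE/EM/ME/MM; returns (category, flags).

    A breakpoint falling outside the stated gene body is flagged
    ``outside-gene`` and treated as M.
    """
    gene5 = annotation.get(call.gene5)
    gene3 = annotation.get(call.gene3)
    if gene5 is None or gene3 is None:
        missing = call.gene5 if gene5 is None else call.gene3
        raise ValidationError(f"call {call.call_id}: gene {missing} missing from annotation")
    flags: list[str] = []

    def side(gene: GeneModel, pos: int, edges: list[int], label: str) -> str:
        if not gene.contains(pos):
            flags.append(f"outside-gene:{label}")
            return "M"
        if any(abs(pos - e) <= edge_tolerance for e in edges):
            return "E"
        return "M"

    side5 = side(gene5, call.breakpoint5, _donor_edges(gene5), "5prime")
    side3 = side(gene3, call.breakpoint3, _acceptor_edges(gene3), "3prime")
    return side5 + side3, flags


def classify_calls(
    calls: Iterable[ChimeraCall],
    annotation: dict[str, GeneModel],
    readthrough_gap: int = DEFAULT_READTHROUGH_GAP,
    edge_tolerance: int = DEFAULT_EDGE_TOLERANCE,
) -> list[ClassifiedCall]:
    """Run both classifiers over a call collection."""
    out = []
    for call in calls:
        cc = ClassifiedCall(call=call)
        cc.location = classify_location(call, annotation, readthrough_gap)
        cc.junction_site, cc.flags = classify_junction_site(call, annotation, edge_tolerance)
        out.append(cc)
    return out


def filter_background(
    calls: Sequence[ChimeraCall],
    panel: BackgroundPanel,
    match_mode: str = "gene-pair",
    breakpoint_tolerance: int = 0,
) -> tuple[list[ChimeraCall], FilterReport]:
    """Remove calls whose key matches the normal-tissue background panel.

    ``gene-pair`` mode keys on the ordered pair gene5->gene3; ``breakpoint``
    mode additionally requires both breakpoints within the tolerance.
    """
    report = FilterReport(n_input=len(calls))
    retained = []
    for call in calls:
        if panel.matches(call, mode=match_mode, breakpoint_tolerance=breakpoint_tolerance):
            report.n_removed_panel += 1
            report.removed.append((call.call_id, "background-panel"))
        else:
            retained.append(call)
    return retained, report


def filter_mm(classified: Sequence[ClassifiedCall]) -> tuple[list[ClassifiedCall], FilterReport]:
    """Drop every MM call; EE/EM/ME are retained."""
    report = FilterReport(n_input=len(classified))
    retained = []
    for cc in classified:
        if cc.junction_site is None:
            raise ValidationError(f"call {cc.call_id}: junction-site classification missing")
        if cc.junction_site == "MM":
            report.n_removed_mm += 1
            report.removed.append((cc.call_id, "MM-junction"))
        else:
            retained.append(cc)
    return retained, report


def category_summary(classified: Sequence[ClassifiedCall]) -> pd.DataFrame:
    """Counts and proportions per category on both classification axes.

    Proportions sum to 1 within each axis. Empty input yields an empty table.
    """
    rows = []
    n = len(classified)
    if n == 0:
        return pd.DataFrame(columns=["axis", "category", "count", "proportion"])
    loc_counts = pd.Series([c.location for c in classified]).value_counts()
    junc_counts = pd.Series([c.junction_site for c in classified]).value_counts()
    for cat in LOCATION_CATEGORIES:
        count = int(loc_counts.get(cat, 0))
        rows.append({"axis": "location", "category": cat, "count": count, "proportion": count / n})
    for cat in JUNCTION_CATEGORIES:
        count = int(junc_counts.get(cat, 0))
        rows.append({"axis": "junction_site", "category": cat, "count": count, "proportion": count / n})
    return pd.DataFrame(rows, columns=["axis", "category", "count", "proportion"])


CLASSIFIED_COLUMNS = [
    "ChimeraID", "GeneName1", "GeneName2", "chr1", "Breakpoint1", "strand1",
    "chr2", "Breakpoint2", "strand2", "crossingreads", "spanningreads",
    "JunctionSequence", "location_category", "junction_site_category", "flags",
]


def classified_to_frame(classified: Sequence[ClassifiedCall]) -> pd.DataFrame:
    """Flat table of classified calls for writing (1-based breakpoints)."""
    rows = []
    for cc in classified:
        c = cc.call
        rows.append(
            {
                "ChimeraID": c.call_id,
                "GeneName1": c.gene5,
                "GeneName2": c.gene3,
                "chr1": c.chrom5,
                "Breakpoint1": c.breakpoint5 + 1,
                "strand1": c.strand5,
                "chr2": c.chrom3,
                "Breakpoint2": c.breakpoint3 + 1,
                "strand2": c.strand3,
                "crossingreads": c.crossing_reads,
                "spanningreads": c.spanning_reads,
                "JunctionSequence": c.junction_seq,
                "location_category": cc.location,
                "junction_site_category": cc.junction_site,
                "flags": ";".join(cc.flags),
            }
        )
    return pd.DataFrame(rows, columns=CLASSIFIED_COLUMNS)
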