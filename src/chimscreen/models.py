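"""Core domain types shared across the pipeline.

Coordinate convention: every genomic interval and breakpoint inside the
package is 0-based. Intervals are half-open ``[start, end)``. External
formats (GTF: 1-based closed; caller TSV breakpoints: 1-based) are converted
at the I/O boundary and nowhere else.

Breakpoints on a :class:`ChimeraCall` follow the transcript reading
direction: ``breakpoint5`` is the genomic position of the *last* transcribed
base of the 5' segment and ``breakpoint3`` the position of the *first*
transcribed base of the 3' segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

LOCATION_CATEGORIES = ("inter-chromosomal", "intra-chromosomal", "read-through")
JUNCTION_CATEGORIES = ("EE", "EM", "ME", "MM")
GROUPS = ("case", "control")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N, case kept)."""
    return seq.translate(COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: exon structure on a single chromosome/strand.

    Exons are 0-based half-open intervals, sorted by start and disjoint
    (book-ended/overlapping records are merged at parse time).
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: exon list is empty")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValidationError(f"gene {self.gene_id}: invalid exon interval [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValidationError(f"gene {self.gene_id}: exons not sorted/disjoint at [{start}, {end})")
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exons_in_transcription_order(self) -> tuple[tuple[int, int], ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def transcript_to_genomic(self, t: int) -> int:
        """Genomic position of transcript offset ``t`` (0-based)."""
        if not 0 <= t < self.transcript_length:
            raise ValidationError(f"gene {self.gene_id}: transcript offset {t} out of range")
        remaining = t
        for start, end in self.exons_in_transcription_order():
            length = end - start
            if remaining < length:
                return start + remaining if self.strand == "+" else end - 1 - remaining
            remaining -= length
        raise AssertionError("unreachable")

    def genomic_to_transcript(self, pos: int) -> int:
        """Transcript offset of genomic position ``pos``; errors if intronic."""
        offset = 0
        for start, end in self.exons_in_transcription_order():
            if start <= pos < end:
                return offset + (pos - start if self.strand == "+" else end - 1 - pos)
            offset += end - start
        raise ValidationError(f"gene {self.gene_id}: position {pos} not exonic")

    def contains(self, pos: int) -> bool:
        """True if pos falls in the gene body (exons or introns)."""
        return self.start <= pos < self.end

    def spliced_sequence(self, chrom_seq: str) -> str:
        """Transcribed (spliced, strand-aware) sequence given the chromosome string."""
        s = "".join(chrom_seq[start:end] for start, end in self.exons)
        return s if self.strand == "+" else revcomp(s)


@dataclass
class ChimeraCall:
    """One candidate chimeric RNA as reported by the upstream caller.

    Read-support counts are caller-reported and carried through verbatim.
    ``junction_split`` is the index of the first 3'-segment base within
    ``junction_seq``.
    """

    call_id: str
    gene5: str
    gene3: str
    chrom5: str
    chrom3: str
    breakpoint5: int
    breakpoint3: int
    strand5: str
    strand3: str
    junction_seq: str
    junction_split: int
    crossing_reads: int = 0
    spanning_reads: int = 0
    caller_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gene5 == self.gene3 and (self.chrom5, self.breakpoint5) == (self.chrom3, self.breakpoint3):
            raise ValidationError(f"call {self.call_id}: identical partners and breakpoints")
        if not 0 < self.junction_split < len(self.junction_seq):
            raise ValidationError(
                f"call {self.call_id}: split index {self.junction_split} not strictly inside junction sequence"
            )
        if self.crossing_reads < 0 or self.spanning_reads < 0:
            raise ValidationError(f"call {self.call_id}: negative read-support counts")
        self.junction_seq = self.junction_seq.upper()

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


@dataclass
class BackgroundPanel:
    """Catalog of chimeras seen across normal tissues, keyed by ordered gene pair.

    The ordered pair A->B is distinct from B->A. Breakpoint coordinates are
    optional and only used in breakpoint match mode.
    """

    entries: dict[tuple[str, str], list[tuple[Optional[int], Optional[int]]]] = field(default_factory=dict)
    source_label: str = ""

    def add(
        self,
        gene5: str,
        gene3: str,
        breakpoint5: Optional[int] = None,
        breakpoint3: Optional[int] = None,
    ) -> None:
        self.entries.setdefault((gene5, gene3), []).append((breakpoint5, breakpoint3))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def matches(
        self,
        call: "ChimeraCall",
        mode: str = "gene-pair",
        breakpoint_tolerance: int = 0,
    ) -> bool:
        pts = self.entries.get(call.gene_pair)
        if pts is None:
            return False
        if mode == "gene-pair":
            return True
        if mode == "breakpoint":
            for bp5, bp3 in pts:
                if bp5 is None or bp3 is None:
                    continue
                if abs(bp5 - call.breakpoint5) <= breakpoint_tolerance and abs(bp3 - call.breakpoint3) <= breakpoint_tolerance:
                    return True
            return False
        raise ValidationError(f"unknown panel match mode {mode!r}")


@dataclass
class SampleSheet:
    """Cohort layout: sample ids, case/control labels, FASTQ paths."""

    samples: list["SampleEntry"]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ids: {', '.join(dup)}")
        for s in self.samples:
            if s.group not in GROUPS:
                raise ValidationError(f"sample {s.sample_id}: group must be one of {GROUPS}, got {s.group!r}")

    def __iter__(self) -> Iterator["SampleEntry"]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def groups(self) -> pd.Series:
        return pd.Series({s.sample_id: s.group for s in self.samples}, name="group")

    def by_group(self, group: str) -> list["SampleEntry"]:
        return [s for s in self.samples if s.group == group]

    def require_both_groups(self) -> None:
        for g in GROUPS:
            if not self.by_group(g):
                raise ValidationError(f"sample sheet has no {g} samples")


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    group: str
    fastq_paths: tuple[str, ...]


@dataclass(frozen=True)
class JunctionProbe:
    """Fixed-length breakpoint-spanning sequence used for read matching.

    ``split_index`` = L/2; the breakpoint lies between ``split_index - 1``
    and ``split_index``. ``call_ids`` lists every call collapsing onto this
    sequence (duplicates share one probe).
    """

    call_ids: tuple[str, ...]
    sequence: str
    split_index: int
    source: str = "from-call"

    def __post_init__(self) -> None:
        length = len(self.sequence)
        if length % 2 != 0:
            raise ValidationError(f"probe {self.call_ids}: length {length} is odd")
        if self.split_index != length // 2:
            raise ValidationError(f"probe {self.call_ids}: split index must equal L/2")
        if "N" in self.sequence:
            raise ValidationError(f"probe {self.call_ids}: contains N")

    @property
    def call_id(self) -> str:
        return self.call_ids[0]


@dataclass(frozen=True)
class MatchParams:
    """Approximate-matching configuration for the junction matcher."""

    k: int = 0
    distance_model: str = "hamming"
    search_reverse_complement: bool = True
    min_flank: int = 0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValidationError(f"k must be non-negative, got {self.k}")
        if self.distance_model not in ("hamming", "edit"):
            raise ValidationError(f"distance_model must be hamming or edit, got {self.distance_model!r}")
        if self.min_flank < 0:
            raise ValidationError("min_flank must be non-negative")


@dataclass
class MatchTable:
    """Samples x probes matrix of junction-supporting read counts."""

    counts: pd.DataFrame  # index: sample_id, columns: call_id, int cells
    groups: pd.Series  # sample_id -> case/control

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)
        self.counts.index.name = "sample_id"
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("match counts must be non-negative")
        self.groups = self.groups.reindex(self.counts.index)
        if self.groups.isna().any():
            missing = list(self.counts.index[self.groups.isna()])
            raise ValidationError(f"samples without group labels: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def chimera_ids(self) -> list[str]:
        return list(self.counts.columns)
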