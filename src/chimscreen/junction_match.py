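"""Junction-probe construction and approximate read matching.

The matcher is an agrep-style bit-parallel (bitap) search. Two distance
models are provided:

* ``hamming`` — shift-and with up to ``k`` substitutions; an occurrence is
  an alignment offset where the probe matches a length-L read substring
  with at most ``k`` mismatching positions.
* ``edit`` — Wu-Manber bitap with substitution/insertion/deletion
  automata; an occurrence is a read end position where the probe matches
  some substring ending there with edit distance at most ``k``.

``N`` bases in reads never match any probe base (they can still be consumed
as errors when ``k > 0``). With ``k == 0`` both models coincide with exact
substring search and a fast path is used; the bitap automata remain the
reference implementation and are cross-checked against a brute-force oracle
in the test suite.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .models import (
    ChimeraCall,
    GeneModel,
    JunctionProbe,
    MatchParams,
    MatchTable,
    SampleSheet,
    ValidationError,
    revcomp,
)

DEFAULT_PROBE_LENGTH = 28


# ---------------------------------------------------------------------------
# probe construction
# ---------------------------------------------------------------------------

@dataclass
class ProbeReport:
    """Audit of probe construction: skips and duplicate collapses."""

    n_calls: int = 0
    n_probes: int = 0
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (call_id, reason)
    collapsed: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)  # (sequence, call_ids)


def _probe_from_call(call: ChimeraCall, length: int) -> str:
    half = length // 2
    seq, split = call.junction_seq, call.junction_split
    if split < half or len(seq) - split < half:
        raise ValidationError(
            f"call {call.call_id}: junction sequence too short for a centered length-{length} probe"
        )
    return seq[split - half : split + half]


def _probe_from_genome(
    call: ChimeraCall,
    length: int,
    genome: dict[str, str],
    annotation: dict[str, GeneModel],
) -> str:
    half = length // 2
    gene5 = annotation.get(call.gene5)
    gene3 = annotation.get(call.gene3)
    if gene5 is None or gene3 is None:
        raise ValidationError(f"call {call.call_id}: parental gene missing from annotation")
    tx5 = gene5.spliced_sequence(genome[gene5.chrom])
    tx3 = gene3.spliced_sequence(genome[gene3.chrom])
    t5 = gene5.genomic_to_transcript(call.breakpoint5)
    t3 = gene3.genomic_to_transcript(call.breakpoint3)
    if t5 + 1 < half:
        raise ValidationError(f"call {call.call_id}: breakpoint5 closer than {half} nt to transcript start")
    if len(tx3) - t3 < half:
        raise ValidationError(f"call {call.call_id}: breakpoint3 closer than {half} nt to transcript end")
    return tx5[t5 + 1 - half : t5 + 1] + tx3[t3 : t3 + half]


def build_probes(
    calls: Iterable[ChimeraCall],
    length: int = DEFAULT_PROBE_LENGTH,
    source: str = "from-call",
    genome: Optional[dict[str, str]] = None,
    annotation: Optional[dict[str, GeneModel]] = None,
) -> tuple[list[JunctionProbe], ProbeReport]:
    """Build fixed-length junction probes, one per distinct sequence.

    ``source`` is ``from-call`` (slice the reported junction sequence around
    its split) or ``from-genome`` (re-extract spliced flanks around the
    breakpoints). Probes containing N are excluded and reported; identical
    probe sequences are collapsed with all contributing call ids recorded.
    """
    if length % 2 != 0:
        raise ValidationError(f"probe length must be even, got {length}")
    if source not in ("from-call", "from-genome"):
        raise ValidationError(f"unknown probe source {source!r}")
    if source == "from-genome" and (genome is None or annotation is None):
        raise ValidationError("from-genome probe construction requires genome and annotation")
    report = ProbeReport()
    by_seq: dict[str, list[str]] = {}
    for call in calls:
        report.n_calls += 1
        try:
            if source == "from-call":
                seq = _probe_from_call(call, length)
            else:
                seq = _probe_from_genome(call, length, genome, annotation)
        except ValidationError as exc:
            report.skipped.append((call.call_id, str(exc)))
            continue
        if "N" in seq:
            report.skipped.append((call.call_id, "probe contains N"))
            continue
        by_seq.setdefault(seq, []).append(call.call_id)
    probes = []
    for seq, ids in by_seq.items():
        if len(ids) > 1:
            report.collapsed.append((seq, tuple(ids)))
        probes.append(
            JunctionProbe(call_ids=tuple(ids), sequence=seq, split_index=length // 2, source=source)
        )
    report.n_probes = len(probes)
    return probes, report


# ---------------------------------------------------------------------------
# bitap matching
# ---------------------------------------------------------------------------

def _char_masks(pattern: str) -> dict[str, int]:
    masks = {c: 0 for c in "ACGT"}
    for i, c in enumerate(pattern):
        if c not in masks:
            raise ValidationError(f"probe contains invalid base {c!r}")
        masks[c] |= 1 << i
    return masks


def _bitap_hamming(pattern: str, text: str, k: int) -> list[int]:
    """End positions (exclusive) of substrings matching with <= k mismatches."""
    m = len(pattern)
    masks = _char_masks(pattern)
    accept = 1 << (m - 1)
    # R[d] bit i: pattern[:i+1] matches text ending here with <= d mismatches
    R = [0] * (k + 1)
    hits = []
    for j, c in enumerate(text):
        mask = masks.get(c, 0)  # N and other letters match nothing
        prev = 0  # R[d-1] before update
        for d in range(k + 1):
            cur = R[d]
            R[d] = (((cur << 1) | 1) & mask) | (((prev << 1) | 1) if d else 0)
            prev = cur
        if R[k] & accept:
            hits.append(j + 1)
    return hits


def _bitap_edit(pattern: str, text: str, k: int) -> list[int]:
    """End positions where edit distance of pattern to a suffix-substring <= k (Wu-Manber)."""
    m = len(pattern)
    masks = _char_masks(pattern)
    accept = 1 << (m - 1)
    R = [(1 << d) - 1 for d in range(k + 1)]  # d leading deletions allowed
    hits = []
    for j, c in enumerate(text):
        mask = masks.get(c, 0)
        prev_old = R[0]
        R[0] = ((R[0] << 1) | 1) & mask
        for d in range(1, k + 1):
            old = R[d]
            # substitution | insertion (consume c) | deletion (skip pattern char)
            R[d] = (((old << 1) | 1) & mask) | ((prev_old << 1) | 1) | prev_old | ((R[d - 1] << 1) | 1)
            prev_old = old
        if R[k] & accept:
            hits.append(j + 1)
    return hits


def _qualifying(hits: list[int], m: int, split: int, text_len: int, min_flank: int) -> int:
    """Count hit end positions whose read flanks around the split point are long enough."""
    if min_flank <= 0:
        return len(hits)
    n = 0
    for end in hits:
        split_pos = end - m + split  # read coordinate of the junction point
        if split_pos >= min_flank and text_len - split_pos >= min_flank:
            n += 1
    return n


def _count_exact(pattern: str, text: str) -> list[int]:
    """Exact-match fast path; equivalent to either bitap model at k=0."""
    hits = []
    start = text.find(pattern)
    while start != -1:
        hits.append(start + len(pattern))
        start = text.find(pattern, start + 1)
    return hits


def bitap_count(probe: JunctionProbe, read: str, params: MatchParams = MatchParams()) -> int:
    """Number of qualifying occurrences of the probe in the read.

    Both orientations are scanned when ``search_reverse_complement`` is on;
    the reverse-complemented probe carries the mirrored split index so the
    ``min_flank`` constraint stays anchored on the junction point.
    """
    m = len(probe.sequence)
    if params.k >= m:
        raise ValidationError(f"k={params.k} must be < probe length {m}")
    read = read.upper()
    total = 0
    scans = [(probe.sequence, probe.split_index)]
    if params.search_reverse_complement:
        scans.append((revcomp(probe.sequence), m - probe.split_index))
    for pattern, split in scans:
        if params.k == 0:
            hits = _count_exact(pattern, read)
        elif params.distance_model == "hamming":
            hits = _bitap_hamming(pattern, read, params.k)
        else:
            hits = _bitap_edit(pattern, read, params.k)
        total += _qualifying(hits, m, split, len(read), params.min_flank)
    return total


# ---------------------------------------------------------------------------
# per-sample and cohort counting
# ---------------------------------------------------------------------------

def count_reads(
    probes: Sequence[JunctionProbe],
    reads: Iterable[tuple[str, str]],
    params: MatchParams = MatchParams(),
) -> dict[str, int]:
    """Per-probe count of reads carrying >= 1 qualifying occurrence.

    A read contributes at most once per probe but may support several
    distinct probes. Deterministic and independent of read order.
    """
    counts = {p.call_id: 0 for p in probes}
    for _, seq in reads:
        for p in probes:
            if bitap_count(p, seq, params) > 0:
                counts[p.call_id] += 1
    return counts


def count_sample(
    probes: Sequence[JunctionProbe],
    fastq_paths: Sequence[str],
    params: MatchParams = MatchParams(),
) -> dict[str, int]:
    """One match-table row: read-level support per probe over a sample's FASTQs."""
    from .formats_io import stream_fastq

    if not probes:
        raise ValidationError("no probes to match")
    return count_reads(probes, stream_fastq(fastq_paths), params)


def count_cohort(
    probes: Sequence[JunctionProbe],
    sample_sheet: SampleSheet,
    params: MatchParams = MatchParams(),
    threads: int = 1,
) -> MatchTable:
    """Samples x probes match table; rows computed independently per sample.

    Thread-parallel over samples when ``threads > 1``; results are assembled
    in sample-sheet order so the table is identical to serial execution.
    """
    samples = list(sample_sheet)

    def row(entry):
        return count_sample(probes, entry.fastq_paths, params)

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            rows = list(pool.map(row, samples))
    else:
        rows = [row(s) for s in samples]
    counts = pd.DataFrame(rows, index=[s.sample_id for s in samples]).astype(int)
    counts = counts[[p.call_id for p in probes]]
    counts.index.name = "sample_id"
    return MatchTable(counts=counts, groups=sample_sheet.groups)
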