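"""Readers and writers for every external format the pipeline touches.

All conversions between file conventions (GTF 1-based closed, caller TSV
1-based breakpoints) and the internal 0-based half-open convention happen
here and only here.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import os
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pandas as pd
from gffutils.feature import feature_from_line
from pyfaidx import Fasta

from .models import (
    BackgroundPanel,
    ChimeraCall,
    GeneModel,
    MatchTable,
    SampleEntry,
    SampleSheet,
    ValidationError,
)

PathLike = Union[str, Path]

CALL_COLUMNS = [
    "GeneName1",
    "GeneName2",
    "chr1",
    "Breakpoint1",
    "strand1",
    "chr2",
    "Breakpoint2",
    "strand2",
    "crossingreads",
    "spanningreads",
    "JunctionSequence",
]
# Optional extensions understood on top of the caller's native columns.
OPTIONAL_CALL_COLUMNS = ["ChimeraID", "JunctionSplit", "EricScore"]

FLOAT_FORMAT = "%.6g"


class ParseError(ValueError):
    """Malformed input file; message carries file and line context."""


class CallCollection(list):
    """List of :class:`ChimeraCall` plus a record of rejected rows."""

    def __init__(self, calls: Iterable[ChimeraCall] = (), rejected: Optional[list] = None):
        super().__init__(calls)
        self.rejected: list[tuple[int, str]] = rejected or []

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


# ---------------------------------------------------------------------------
# annotation (GTF)
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort and merge book-ended or overlapping intervals."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def read_annotation(path: PathLike) -> list[GeneModel]:
    """Parse exon records from a GTF/GFF file into :class:`GeneModel` objects.

    GTF 1-based closed coordinates become 0-based half-open. Exons of one
    gene are merged when book-ended or overlapping. Output is sorted by
    (chrom, start, gene_id).
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ParseError(f"{path}:{lineno}: malformed GTF line (expected 9 tab-separated fields)")
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}:{lineno}: malformed GTF line ({exc})") from exc
            if feat.featuretype != "exon":
                continue
            if feat.end < feat.start:
                raise ValidationError(f"{path}:{lineno}: exon end {feat.end} < start {feat.start}")
            gene_id = feat.attributes.get("gene_id", [None])[0]
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: exon record lacks gene_id attribute")
            symbol = feat.attributes.get("gene_name", [gene_id])[0]
            rec = genes.setdefault(
                gene_id, {"symbol": symbol, "chrom": feat.seqid, "strand": feat.strand, "exons": []}
            )
            if rec["chrom"] != feat.seqid:
                raise ValidationError(
                    f"gene {gene_id} spans two chromosomes ({rec['chrom']} and {feat.seqid})"
                )
            if rec["strand"] != feat.strand:
                raise ValidationError(f"gene {gene_id} has exons on both strands")
            rec["exons"].append((feat.start - 1, feat.end))  # 1-based closed -> 0-based half-open
    models = [
        GeneModel(
            gene_id=gid,
            symbol=rec["symbol"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=_merge_intervals(rec["exons"]),
        )
        for gid, rec in genes.items()
    ]
    models.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return models


def write_annotation(genes: Sequence[GeneModel], path: PathLike, source: str = "chimscreen") -> None:
    """Write exon records as GTF (1-based closed)."""
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            for start, end in gene.exons:
                attrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.symbol}";'
                fh.write(
                    f"{gene.chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t{gene.strand}\t.\t{attrs}\n"
                )


def annotation_index(genes: Iterable[GeneModel]) -> dict[str, GeneModel]:
    """Index genes by symbol (and gene_id) for call classification."""
    idx: dict[str, GeneModel] = {}
    for g in genes:
        idx[g.symbol] = g
        idx.setdefault(g.gene_id, g)
    return idx


# ---------------------------------------------------------------------------
# chimera call tables (caller-style TSV)
# ---------------------------------------------------------------------------

def read_calls(path: PathLike) -> CallCollection:
    """Read a caller-style TSV of chimera candidates.

    File breakpoints are 1-based and converted to the internal 0-based
    convention. The junction split index defaults to the midpoint of an
    even-length junction sequence; a ``JunctionSplit`` column (number of
    5'-side bases) overrides it. Rows that cannot be parsed are rejected and
    reported on the returned collection, not raised.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    calls = CallCollection()
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        try:
            calls.append(_parse_call_row(row, lineno))
        except (ValidationError, ParseError, TypeError) as exc:
            calls.rejected.append((lineno, str(exc)))
    return calls


def _parse_call_row(row: pd.Series, lineno: int) -> ChimeraCall:
    try:
        bp1 = int(row["Breakpoint1"])
        bp2 = int(row["Breakpoint2"])
    except (TypeError, ValueError):
        raise ParseError(f"line {lineno}: unparseable breakpoint coordinates")
    seq = str(row["JunctionSequence"]).upper()
    if not seq or seq == "NAN":
        raise ParseError(f"line {lineno}: missing junction sequence")
    split_raw = row.get("JunctionSplit")
    if split_raw is not None and not pd.isna(split_raw):
        split = int(split_raw)
    elif len(seq) % 2 == 0:
        split = len(seq) // 2
    else:
        raise ParseError(f"line {lineno}: odd-length junction sequence without a split marker")
    call_id = row.get("ChimeraID")
    if call_id is None or pd.isna(call_id):
        call_id = f"{row['GeneName1']}--{row['GeneName2']}@{lineno}"
    score_raw = row.get("EricScore")
    score = float(score_raw) if score_raw is not None and not pd.isna(score_raw) else None
    return ChimeraCall(
        call_id=str(call_id),
        gene5=str(row["GeneName1"]),
        gene3=str(row["GeneName2"]),
        chrom5=str(row["chr1"]),
        chrom3=str(row["chr2"]),
        breakpoint5=bp1 - 1,
        breakpoint3=bp2 - 1,
        strand5=str(row["strand1"]),
        strand3=str(row["strand2"]),
        junction_seq=seq,
        junction_split=split,
        crossing_reads=int(row["crossingreads"]),
        spanning_reads=int(row["spanningreads"]),
        caller_score=score,
    )


def write_calls(calls: Iterable[ChimeraCall], path: PathLike) -> None:
    """Write calls in the caller-style TSV format (1-based breakpoints)."""
    rows = []
    for c in calls:
        rows.append(
            {
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
                "ChimeraID": c.call_id,
                "JunctionSplit": c.junction_split,
                "EricScore": "" if c.caller_score is None else c.caller_score,
            }
        )
    cols = CALL_COLUMNS + OPTIONAL_CALL_COLUMNS
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# background panel
# ---------------------------------------------------------------------------

def read_panel(path: PathLike, source_label: str = "") -> BackgroundPanel:
    """Panel TSV: columns gene5, gene3, optional breakpoint5/breakpoint3 (1-based)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene5", "gene3"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column(s): {col}")
    panel = BackgroundPanel(source_label=source_label)
    for _, row in df.iterrows():
        bp5 = row.get("breakpoint5")
        bp3 = row.get("breakpoint3")
        panel.add(
            str(row["gene5"]),
            str(row["gene3"]),
            None if bp5 is None or pd.isna(bp5) else int(bp5) - 1,
            None if bp3 is None or pd.isna(bp3) else int(bp3) - 1,
        )
    return panel


def write_panel(panel: BackgroundPanel, path: PathLike) -> None:
    rows = []
    for (g5, g3), pts in sorted(panel.entries.items()):
        for bp5, bp3 in pts:
            rows.append(
                {
                    "gene5": g5,
                    "gene3": g3,
                    "breakpoint5": "" if bp5 is None else bp5 + 1,
                    "breakpoint3": "" if bp3 is None else bp3 + 1,
                }
            )
    pd.DataFrame(rows, columns=["gene5", "gene3", "breakpoint5", "breakpoint3"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path: PathLike, check_paths: bool = True) -> SampleSheet:
    """TSV with columns sample_id, group, fastq_paths (comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group", "fastq_paths"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column(s): {col}")
    base = Path(path).parent
    entries = []
    for _, row in df.iterrows():
        paths = tuple(
            str(p if os.path.isabs(p) else base / p)
            for p in str(row["fastq_paths"]).split(",")
            if p
        )
        if check_paths:
            for p in paths:
                if not os.path.exists(p):
                    raise ValidationError(f"sample {row['sample_id']}: FASTQ path does not exist: {p}")
        entries.append(SampleEntry(str(row["sample_id"]), str(row["group"]), paths))
    sheet = SampleSheet(entries)
    sheet.require_both_groups()
    return sheet


def write_sample_sheet(sheet: SampleSheet, path: PathLike, relative_to: Optional[PathLike] = None) -> None:
    rows = []
    for s in sheet:
        paths = s.fastq_paths
        if relative_to is not None:
            paths = tuple(os.path.relpath(p, relative_to) for p in paths)
        rows.append({"sample_id": s.sample_id, "group": s.group, "fastq_paths": ",".join(paths)})
    pd.DataFrame(rows, columns=["sample_id", "group", "fastq_paths"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    """Load a FASTA file into an uppercased name -> sequence dict."""
    with Fasta(str(path)) as fa:
        return {name: str(rec[:]).upper() for name, rec in fa.items()}


def write_fasta(sequences: dict[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _text_writer(raw):
    import io

    return io.TextIOWrapper(raw, encoding="ascii", newline="\n")


def _open_maybe_gzip(path: PathLike):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "r")


def stream_fastq(paths: Sequence[PathLike]) -> Iterator[tuple[str, str]]:
    """Yield (read_id, uppercased sequence) for every record across files.

    Plain and gzip-compressed files are handled transparently. Four-line
    records only; quality strings are length-checked then dropped. Paired-end
    mates are just independent reads here.
    """
    for path in paths:
        with _open_maybe_gzip(path) as fh:
            record_index = 0
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline()
                plus = fh.readline()
                qual = fh.readline()
                if not qual:
                    raise ParseError(f"{path}: truncated FASTQ record at index {record_index}")
                header = header.rstrip("\n")
                seq = seq.rstrip("\n")
                qual = qual.rstrip("\n")
                if not header.startswith("@"):
                    raise ParseError(f"{path}: record {record_index} does not start with '@'")
                if not plus.startswith("+"):
                    raise ParseError(f"{path}: record {record_index} missing '+' separator line")
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path}: record {record_index} sequence/quality length mismatch "
                        f"({len(seq)} vs {len(qual)})"
                    )
                yield header[1:].split()[0], seq.upper()
                record_index += 1


def write_fastq(reads: Iterable[tuple[str, str]], path: PathLike, quality_char: str = "I") -> int:
    """Write (read_id, sequence) records with constant quality; returns count."""
    if str(path).endswith(".gz"):
        # mtime pinned to 0 so identical runs give byte-identical files
        def opener(p, mode):
            return gzip.GzipFile(p, "wb", mtime=0)
    else:
        opener = open
    n = 0
    with opener(path, "wb") as raw, _text_writer(raw) as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# match tables and result writing
# ---------------------------------------------------------------------------

def write_match_table(table: MatchTable, path: PathLike) -> None:
    out = table.counts.copy()
    out.insert(0, "group", table.groups)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_match_table(path: PathLike) -> MatchTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "group" not in df.columns:
        raise ParseError(f"{path}: missing group column")
    groups = df["group"]
    counts = df.drop(columns=["group"]).astype(int)
    return MatchTable(counts=counts, groups=groups)


def file_sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: PathLike,
    params: Optional[dict] = None,
    seed: Optional[int] = None,
    input_paths: Sequence[PathLike] = (),
) -> dict[str, Path]:
    """Write result tables as TSV plus a run-metadata JSON file.

    Output is deterministic: fixed column order as given, fixed float
    precision, metadata limited to parameters, seed, and input hashes (no
    timestamps), so identical runs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written[name] = path
    metadata = {
        "params": params or {},
        "seed": seed,
        "inputs": {os.path.basename(str(p)): file_sha256(p) for p in input_paths},
    }
    meta_path = out_dir / "run_metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["run_metadata"] = meta_path
    return written
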