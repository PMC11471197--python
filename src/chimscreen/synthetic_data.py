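"""Self-contained synthetic test universe.

Generates a toy genome with multi-exon genes, plants chimeric transcripts
with an exactly controlled mix of location and junction-site categories,
simulates case/control FASTQ read sets with substitution errors, and keeps
a truth ledger so every downstream stage has an exact oracle.

Guarantees engineered into the generator (and relied on by the tests):

* full determinism under a fixed seed;
* category mixes realized exactly via largest-remainder rounding;
* every planted junction probe is verified absent — at the matcher's
  default setting — from the genome (both orientations), every normal
  transcript, and every other chimeric transcript, with breakpoints redrawn
  on collision, so non-expressed probes count exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import formats_io
from .catalog import DEFAULT_READTHROUGH_GAP, _gap_in_transcription_order
from .models import (
    ChimeraCall,
    GeneModel,
    JUNCTION_CATEGORIES,
    LOCATION_CATEGORIES,
    SampleEntry,
    SampleSheet,
    ValidationError,
    revcomp,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """All knobs of the synthetic universe; defaults mirror the study design
    of a 4-case / 4-control placenta cohort."""

    seed: int = 0
    n_chromosomes: int = 4
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_len: tuple[int, int] = (60, 100)
    intron_len: tuple[int, int] = (40, 80)
    intergenic_gap: tuple[int, int] = (100, 300)
    n_chimeras: int = 30
    category_mix: dict = field(
        default_factory=lambda: {
            "inter-chromosomal": 0.4,
            "intra-chromosomal": 0.3,
            "read-through": 0.3,
        }
    )
    junction_site_mix: dict = field(
        default_factory=lambda: {"EE": 0.4, "EM": 0.2, "ME": 0.2, "MM": 0.2}
    )
    n_background_panel: int = 5
    n_panel_extra: int = 3
    n_decoys: int = 3
    probe_length: int = 28
    read_length: int = 75
    anchor: Optional[int] = None  # default probe_length // 2
    error_rate: float = 0.0
    junction_coverage: float = 4.0
    background_reads_per_sample: int = 200
    n_case: int = 4
    n_control: int = 4
    group_exclusive: tuple[int, int] = (4, 4)  # (case-only, control-only)
    guarantee_detection: bool = True
    readthrough_gap: int = DEFAULT_READTHROUGH_GAP
    gzip_fastq: bool = False

    def __post_init__(self) -> None:
        if self.anchor is None:
            self.anchor = self.probe_length // 2
        for name, mix, cats in (
            ("category_mix", self.category_mix, LOCATION_CATEGORIES),
            ("junction_site_mix", self.junction_site_mix, JUNCTION_CATEGORIES),
        ):
            if set(mix) - set(cats):
                raise ValidationError(f"{name}: unknown categories {set(mix) - set(cats)}")
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"{name}: proportions sum to {total}, expected 1.0")
            if any(v < 0 for v in mix.values()):
                raise ValidationError(f"{name}: negative proportion")
        for name in (
            "n_chromosomes", "n_genes", "n_chimeras", "n_background_panel", "n_panel_extra",
            "n_decoys", "read_length", "background_reads_per_sample", "n_case", "n_control",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not 0 <= self.error_rate < 1:
            raise ValidationError("error_rate must be in [0, 1)")
        if self.probe_length % 2 != 0:
            raise ValidationError("probe_length must be even")
        if self.read_length < 2 * self.anchor:
            raise ValidationError("read_length must be at least twice the junction anchor")
        if sum(self.group_exclusive) > self.n_chimeras:
            raise ValidationError("group_exclusive counts exceed n_chimeras")
        if self.n_background_panel > self.n_chimeras:
            raise ValidationError("n_background_panel exceeds n_chimeras")
        if self.junction_coverage < 0:
            raise ValidationError("junction_coverage must be non-negative")


@dataclass
class TruthTable:
    """Ledger of planted chimeras and realized per-sample junction coverage."""

    info: pd.DataFrame  # index call_id: categories, panel flag, group label, expected coverage
    realized: pd.DataFrame  # samples x call_id realized junction-read counts

    def write(self, out_dir: Path) -> None:
        info = self.info.copy()
        info.index.name = "call_id"
        info.to_csv(out_dir / "truth_info.tsv", sep="\t")
        realized = self.realized.copy()
        realized.index.name = "sample_id"
        realized.to_csv(out_dir / "truth_realized.tsv", sep="\t")

    @classmethod
    def read(cls, out_dir: Path) -> "TruthTable":
        info = pd.read_csv(out_dir / "truth_info.tsv", sep="\t", index_col="call_id")
        realized = pd.read_csv(out_dir / "truth_realized.tsv", sep="\t", index_col="sample_id")
        return cls(info=info, realized=realized)


def largest_remainder(proportions: dict, total: int) -> dict:
    """Integer apportionment of ``total`` following the proportions exactly."""
    quotas = {k: v * total for k, v in proportions.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = total - sum(counts.values())
    # ties broken by key order for determinism
    order = sorted(quotas, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in order[:short]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def simulate_genome(config: SimConfig, rng: Optional[np.random.Generator] = None) -> tuple[dict[str, str], list[GeneModel]]:
    """Uniform-ACGT chromosomes with non-overlapping multi-exon genes on both strands."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genes: list[GeneModel] = []
    genome: dict[str, str] = {}
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    gene_no = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        cursor = int(rng.integers(*config.intergenic_gap, endpoint=True))
        for _ in range(per_chrom[ci]):
            gene_no += 1
            n_exons = int(rng.integers(*config.exons_per_gene, endpoint=True))
            exons = []
            pos = cursor
            for e in range(n_exons):
                if e > 0:
                    pos += int(rng.integers(*config.intron_len, endpoint=True))
                length = int(rng.integers(*config.exon_len, endpoint=True))
                exons.append((pos, pos + length))
                pos = exons[-1][1]
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"G{gene_no:03d}",
                    symbol=f"GENE{gene_no:03d}",
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(exons),
                )
            )
            cursor = pos + int(rng.integers(*config.intergenic_gap, endpoint=True))
        genome[chrom] = _random_seq(rng, cursor)
    short = [g.gene_id for g in genes if g.transcript_length < config.read_length]
    if short:
        raise ValidationError(
            f"read_length {config.read_length} exceeds transcript length of gene(s) {short}; "
            "increase exon_len/exons_per_gene or lower read_length"
        )
    return genome, genes


# ---------------------------------------------------------------------------
# chimera planting
# ---------------------------------------------------------------------------

def _readthrough_pairs(genes: list[GeneModel], gap_limit: int) -> list[tuple[GeneModel, GeneModel]]:
    """Adjacent same-strand gene pairs in transcription order with gap <= limit."""
    pairs = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes = sorted(chrom_genes, key=lambda g: g.start)
        for left, right in zip(chrom_genes, chrom_genes[1:]):
            if left.strand != right.strand:
                continue
            g5, g3 = (left, right) if left.strand == "+" else (right, left)
            gap = _gap_in_transcription_order(g5, g3)
            if gap is not None and gap <= gap_limit:
                pairs.append((g5, g3))
    return pairs


def _pick_gene_pair(
    rng: np.random.Generator,
    location: str,
    genes: list[GeneModel],
    rt_pairs: list[tuple[GeneModel, GeneModel]],
    used_pairs: set,
    gap_limit: int,
    max_tries: int = 500,
) -> tuple[GeneModel, GeneModel]:
    for _ in range(max_tries):
        if location == "read-through":
            if not rt_pairs:
                raise ValidationError("no same-strand adjacent gene pairs available for read-through planting")
            g5, g3 = rt_pairs[int(rng.integers(len(rt_pairs)))]
        elif location == "inter-chromosomal":
            g5, g3 = (genes[int(i)] for i in rng.choice(len(genes), size=2, replace=False))
            if g5.chrom == g3.chrom:
                continue
        else:  # intra-chromosomal: same chromosome but not read-through-compatible
            g5, g3 = (genes[int(i)] for i in rng.choice(len(genes), size=2, replace=False))
            if g5.chrom != g3.chrom:
                continue
            if g5.strand == g3.strand:
                gap = _gap_in_transcription_order(g5, g3)
                if gap is not None and gap <= gap_limit:
                    continue
        if (g5.symbol, g3.symbol) in used_pairs:
            continue
        used_pairs.add((g5.symbol, g3.symbol))
        return g5, g3
    raise ValidationError(f"could not place a {location} chimera; annotation too small for the mix")


def _pick_breakpoint5(rng: np.random.Generator, gene: GeneModel, side: str, min_prefix: int) -> int:
    """Transcript offset of the last 5'-segment base (prefix length - 1)."""
    exons = gene.exons_in_transcription_order()
    cum = 0
    choices = []
    for start, end in exons:
        length = end - start
        if side == "E":
            if cum + length >= min_prefix:
                choices.append(cum + length - 1)  # donor edge of this exon
        else:
            lo = max(2, min_prefix - 1 - cum)
            hi = length - 3
            if lo <= hi:
                choices.append((cum, lo, hi))
        cum += length
    if not choices:
        raise ValidationError(f"gene {gene.symbol}: no valid {side} 5' breakpoint")
    pick = choices[int(rng.integers(len(choices)))]
    if side == "E":
        return pick
    cum, lo, hi = pick
    return cum + int(rng.integers(lo, hi + 1))


def _pick_breakpoint3(rng: np.random.Generator, gene: GeneModel, side: str, min_suffix: int) -> int:
    """Transcript offset of the first 3'-segment base."""
    exons = gene.exons_in_transcription_order()
    total = gene.transcript_length
    cum = 0
    choices = []
    for start, end in exons:
        length = end - start
        if side == "E":
            if total - cum >= min_suffix:
                choices.append(cum)  # acceptor edge of this exon
        else:
            lo = 2
            hi = min(length - 3, total - min_suffix - cum)
            if lo <= hi:
                choices.append((cum, lo, hi))
        cum += length
    if not choices:
        raise ValidationError(f"gene {gene.symbol}: no valid {side} 3' breakpoint")
    pick = choices[int(rng.integers(len(choices)))]
    if side == "E":
        return pick
    cum, lo, hi = pick
    return cum + int(rng.integers(lo, hi + 1))


def _contains_either_orientation(needle: str, haystack: str) -> bool:
    return needle in haystack or revcomp(needle) in haystack


def plant_chimeras(
    config: SimConfig,
    annotation: list[GeneModel],
    genome: dict[str, str],
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, str], list[ChimeraCall], pd.DataFrame]:
    """Plant chimeric transcripts matching the configured category mixes.

    Returns (chimeric transcript sequences by call_id, calls, truth info
    frame). Decoy chimeras (never expressed) are appended after the
    ``n_chimeras`` regular ones.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    half = config.probe_length // 2
    loc_counts = largest_remainder(config.category_mix, config.n_chimeras)
    junc_counts = largest_remainder(config.junction_site_mix, config.n_chimeras)
    loc_labels = [c for c in LOCATION_CATEGORIES for _ in range(loc_counts.get(c, 0))]
    junc_labels = [c for c in JUNCTION_CATEGORIES for _ in range(junc_counts.get(c, 0))]
    rng.shuffle(junc_labels)
    e_case, e_control = config.group_exclusive
    group_labels = (
        ["case_exclusive"] * e_case
        + ["control_exclusive"] * e_control
        + ["shared"] * (config.n_chimeras - e_case - e_control)
    )
    order = rng.permutation(config.n_chimeras)
    group_labels = [group_labels[i] for i in order]
    panel_ids = set(rng.choice(config.n_chimeras, size=config.n_background_panel, replace=False).tolist())

    plan = [
        (f"CHIM{i + 1:03d}", loc_labels[i], junc_labels[i], group_labels[i], i in panel_ids)
        for i in range(config.n_chimeras)
    ]
    for d in range(config.n_decoys):
        loc = LOCATION_CATEGORIES[d % len(LOCATION_CATEGORIES)]
        junc = ("EE", "EM", "ME")[d % 3]  # decoys stay out of the MM filter path
        plan.append((f"DECOY{d + 1:02d}", loc, junc, "decoy", False))

    rt_pairs = _readthrough_pairs(annotation, config.readthrough_gap)
    used_pairs: set = set()
    spliced_cache = {g.symbol: g.spliced_sequence(genome[g.chrom]) for g in annotation}
    transcripts: dict[str, str] = {}
    calls: list[ChimeraCall] = []
    truth_rows = []
    min_seg = max(half, config.anchor)

    for call_id, location, junc, group_label, in_panel in plan:
        for attempt in range(200):
            g5, g3 = _pick_gene_pair(rng, location, annotation, rt_pairs, used_pairs, config.readthrough_gap)
            try:
                t5 = _pick_breakpoint5(rng, g5, junc[0], min_prefix=min_seg)
                t3 = _pick_breakpoint3(rng, g3, junc[1], min_suffix=min_seg)
            except ValidationError:
                used_pairs.discard((g5.symbol, g3.symbol))
                continue
            tx5, tx3 = spliced_cache[g5.symbol], spliced_cache[g3.symbol]
            chim = tx5[: t5 + 1] + tx3[t3:]
            if len(chim) < config.read_length:
                used_pairs.discard((g5.symbol, g3.symbol))
                continue
            junction_seq = chim[t5 + 1 - half : t5 + 1 + half]
            clash = (
                any(_contains_either_orientation(junction_seq, c) for c in genome.values())
                or any(_contains_either_orientation(junction_seq, s) for s in spliced_cache.values())
                or any(_contains_either_orientation(junction_seq, t) for t in transcripts.values())
                or any(_contains_either_orientation(c.junction_seq, chim) for c in calls)
            )
            if clash:
                used_pairs.discard((g5.symbol, g3.symbol))
                continue
            break
        else:
            raise ValidationError(f"could not plant {call_id} ({location}/{junc}) without probe collisions")
        support = max(1, int(round(config.junction_coverage)))
        call = ChimeraCall(
            call_id=call_id,
            gene5=g5.symbol,
            gene3=g3.symbol,
            chrom5=g5.chrom,
            chrom3=g3.chrom,
            breakpoint5=g5.transcript_to_genomic(t5),
            breakpoint3=g3.transcript_to_genomic(t3),
            strand5=g5.strand,
            strand3=g3.strand,
            junction_seq=junction_seq,
            junction_split=half,
            crossing_reads=support,
            spanning_reads=support,
            caller_score=None,
        )
        calls.append(call)
        transcripts[call_id] = chim
        truth_rows.append(
            {
                "call_id": call_id,
                "gene5": g5.symbol,
                "gene3": g3.symbol,
                "location_category": location,
                "junction_site_category": junc,
                "panel_member": in_panel,
                "group_label": group_label,
                "expected_coverage": 0.0 if group_label == "decoy" else config.junction_coverage,
                "junction_seq": junction_seq,
                "breakpoint_offset": t5 + 1,  # transcript coordinate of the first 3' base
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("call_id")
    return transcripts, calls, truth


def build_panel(
    config: SimConfig,
    calls: Sequence[ChimeraCall],
    truth: pd.DataFrame,
    annotation: list[GeneModel],
    rng: np.random.Generator,
):
    """Background panel: the planted panel members plus unrelated gene pairs."""
    from .models import BackgroundPanel

    panel = BackgroundPanel(source_label="synthetic normal-tissue panel")
    call_pairs = {(c.gene5, c.gene3) for c in calls}
    for c in calls:
        if truth.loc[c.call_id, "panel_member"]:
            panel.add(c.gene5, c.gene3, c.breakpoint5, c.breakpoint3)
    added = 0
    while added < config.n_panel_extra:
        i, j = rng.choice(len(annotation), size=2, replace=False)
        pair = (annotation[int(i)].symbol, annotation[int(j)].symbol)
        if pair in call_pairs or pair in panel.entries:
            continue
        panel.add(*pair)
        added += 1
    return panel


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < error_rate
    if not hit.any():
        return seq
    idx = np.flatnonzero(hit)
    for i in idx:
        alternatives = BASES[BASES != arr[i]]
        arr[i] = alternatives[int(rng.integers(3))]
    return arr.tobytes().decode()


def _expressed_in(group_label: str, group: str) -> bool:
    if group_label == "decoy":
        return False
    if group_label == "case_exclusive":
        return group == "case"
    if group_label == "control_exclusive":
        return group == "control"
    return True


def simulate_reads(
    config: SimConfig,
    genome: dict[str, str],
    annotation: list[GeneModel],
    transcripts: dict[str, str],
    truth: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Per-sample reads plus the realized junction-coverage matrix.

    Background reads are uniform draws from normal spliced transcripts.
    Junction-spanning reads overlap the breakpoint by at least the anchor on
    each side, with per-chimera per-sample counts ~ Poisson(junction_coverage)
    (zero when the chimera is not expressed in the sample's group). Roughly
    half of all reads are emitted reverse-complemented.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sample_ids = [f"case_{i + 1}" for i in range(config.n_case)] + [
        f"control_{i + 1}" for i in range(config.n_control)
    ]
    groups = {s: ("case" if s.startswith("case") else "control") for s in sample_ids}
    normal_txs = [
        (g.symbol, g.spliced_sequence(genome[g.chrom]))
        for g in annotation
        if g.transcript_length >= config.read_length
    ]
    L = config.read_length
    anchor = config.anchor

    # draw counts first so detection guarantees can be patched in before emission
    counts = pd.DataFrame(0, index=sample_ids, columns=truth.index, dtype=int)
    for call_id, row in truth.iterrows():
        for s in sample_ids:
            if _expressed_in(row["group_label"], groups[s]):
                counts.loc[s, call_id] = int(rng.poisson(config.junction_coverage))
    if config.guarantee_detection:
        for call_id, row in truth.iterrows():
            for group in ("case", "control"):
                members = [s for s in sample_ids if groups[s] == group]
                if not members or not _expressed_in(row["group_label"], group):
                    continue
                if counts.loc[members, call_id].sum() == 0:
                    counts.loc[members[0], call_id] = 1

    reads_by_sample: dict[str, list[tuple[str, str]]] = {}
    for s in sample_ids:
        reads: list[tuple[str, str]] = []
        for i in range(config.background_reads_per_sample):
            sym, tx = normal_txs[int(rng.integers(len(normal_txs)))]
            start = int(rng.integers(0, len(tx) - L + 1))
            reads.append((f"{s}:bg:{i}", tx[start : start + L]))
        for call_id, row in truth.iterrows():
            n = int(counts.loc[s, call_id])
            if n == 0:
                continue
            tx = transcripts[call_id]
            j = int(row["breakpoint_offset"])  # first base of the 3' segment
            lo = max(0, j - L + anchor)
            hi = min(len(tx) - L, j - anchor)
            if lo > hi:
                raise ValidationError(f"{call_id}: no valid junction-read window (transcript too short)")
            for i in range(n):
                start = int(rng.integers(lo, hi + 1))
                reads.append((f"{s}:junc:{call_id}:{i}", tx[start : start + L]))
        # errors and orientation applied in one deterministic pass
        final = []
        for read_id, seq in reads:
            seq = _apply_errors(seq, config.error_rate, rng)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            final.append((read_id, seq))
        reads_by_sample[s] = final
    return reads_by_sample, counts


# ---------------------------------------------------------------------------
# dataset orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Everything the generator produced, in memory and on disk."""

    config: SimConfig
    genome: dict[str, str]
    annotation: list[GeneModel]
    transcripts: dict[str, str]
    calls: list[ChimeraCall]
    panel: "object"
    truth: TruthTable
    sample_sheet: SampleSheet
    paths: dict[str, Path]


def simulate_dataset(config: SimConfig, out_dir) -> SimResult:
    """Run the full generator and write every artifact under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome, annotation = simulate_genome(config, rng)
    transcripts, calls, truth_info = plant_chimeras(config, annotation, genome, rng)
    panel = build_panel(config, calls, truth_info, annotation, rng)
    reads_by_sample, realized = simulate_reads(config, genome, annotation, transcripts, truth_info, rng)

    paths: dict[str, Path] = {}
    paths["genome"] = out_dir / "genome.fa"
    formats_io.write_fasta(genome, paths["genome"])
    paths["annotation"] = out_dir / "annotation.gtf"
    formats_io.write_annotation(annotation, paths["annotation"])
    paths["transcripts"] = out_dir / "chimeric_transcripts.fa"
    formats_io.write_fasta(transcripts, paths["transcripts"])
    paths["calls"] = out_dir / "calls.tsv"
    formats_io.write_calls(calls, paths["calls"])
    paths["panel"] = out_dir / "panel.tsv"
    formats_io.write_panel(panel, paths["panel"])

    entries = []
    ext = ".fastq.gz" if config.gzip_fastq else ".fastq"
    for sample_id, reads in reads_by_sample.items():
        fq = out_dir / f"{sample_id}{ext}"
        formats_io.write_fastq(reads, fq)
        group = "case" if sample_id.startswith("case") else "control"
        entries.append(SampleEntry(sample_id, group, (str(fq),)))
    sheet = SampleSheet(entries)
    paths["sample_sheet"] = out_dir / "samples.tsv"
    formats_io.write_sample_sheet(sheet, paths["sample_sheet"], relative_to=out_dir)

    truth = TruthTable(info=truth_info, realized=realized)
    truth.write(out_dir)
    paths["truth_info"] = out_dir / "truth_info.tsv"
    paths["truth_realized"] = out_dir / "truth_realized.tsv"

    cfg = asdict(config)
    with open(out_dir / "sim_config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    paths["config"] = out_dir / "sim_config.json"
    return SimResult(
        config=config,
        genome=genome,
        annotation=annotation,
        transcripts=transcripts,
        calls=calls,
        panel=panel,
        truth=truth,
        sample_sheet=sheet,
        paths=paths,
    )
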