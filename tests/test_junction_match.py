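import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import edit_occurrences, hamming_occurrences

from chimscreen import formats_io
from chimscreen.junction_match import (
    _bitap_edit,
    _bitap_hamming,
    _count_exact,
    bitap_count,
    build_probes,
    count_cohort,
    count_reads,
    count_sample,
)
from chimscreen.models import (
    ChimeraCall,
    JunctionProbe,
    MatchParams,
    SampleEntry,
    SampleSheet,
    ValidationError,
    revcomp,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


def make_probe(seq, source="from-call"):
    return JunctionProbe(call_ids=("P1",), sequence=seq, split_index=len(seq) // 2, source=source)


def make_call(seq, split=None, call_id="C1"):
    return ChimeraCall(
        call_id=call_id,
        gene5="A",
        gene3="B",
        chrom5="chr1",
        chrom3="chr2",
        breakpoint5=100,
        breakpoint3=200,
        strand5="+",
        strand3="+",
        junction_seq=seq,
        junction_split=len(seq) // 2 if split is None else split,
    )


class TestBuildProbes:
    def test_identity_when_lengths_match(self):
        seq = "ACGTACGTACGTAACCGGTTACGTACGT"
        (probe,), report = build_probes([make_call(seq)], length=28)
        assert probe.sequence == seq
        assert probe.split_index == 14
        assert report.n_probes == 1

    def test_centered_slice_of_longer_junction(self):
        seq = "G" * 5 + "ACGTACGTACGTAACCGGTTACGTACGT" + "T" * 5
        (probe,), _ = build_probes([make_call(seq)], length=28)
        assert probe.sequence == "ACGTACGTACGTAACCGGTTACGTACGT"

    def test_short_junction_skipped_with_reason(self):
        probes, report = build_probes([make_call("ACGTACGTAC")], length=28)
        assert probes == []
        assert report.skipped[0][0] == "C1"

    def test_probe_with_n_excluded(self):
        seq = "ACGTACGTACGTANCCGGTTACGTACGT"
        probes, report = build_probes([make_call(seq)], length=28)
        assert probes == []
        assert "N" in report.skipped[0][1]

    def test_duplicates_collapsed(self):
        seq = "ACGTACGTACGTAACCGGTTACGTACGT"
        probes, report = build_probes([make_call(seq, call_id="C1"), make_call(seq, call_id="C2")])
        assert len(probes) == 1
        assert probes[0].call_ids == ("C1", "C2")
        assert report.collapsed == [(seq, ("C1", "C2"))]

    def test_odd_length_config_error(self):
        with pytest.raises(ValidationError, match="even"):
            build_probes([make_call("ACGT" * 7)], length=27)

    def test_from_genome_matches_planted_junctions(self, sim, annotation_index):
        probes, report = build_probes(
            sim.calls,
            length=28,
            source="from-genome",
            genome=sim.genome,
            annotation=annotation_index,
        )
        assert not report.skipped
        by_id = {p.call_id: p for p in probes for _ in p.call_ids}
        for call in sim.calls:
            expected = sim.truth.info.loc[call.call_id, "junction_seq"]
            found = next(p for p in probes if call.call_id in p.call_ids)
            assert found.sequence == expected


# deliberately not its own reverse complement
PROBE28 = "AAAACCCCGGGGTTTTAAAACCCCGGGG"
assert revcomp(PROBE28) != PROBE28


class TestBitapCount:
    def test_exact_self_match(self):
        probe = make_probe(PROBE28)
        assert bitap_count(probe, PROBE28, MatchParams(k=0)) == 1

    def test_single_substitution_needs_k1(self):
        read = PROBE28[:15] + ("A" if PROBE28[15] != "A" else "C") + PROBE28[16:]
        probe = make_probe(PROBE28)
        assert bitap_count(probe, read, MatchParams(k=0, search_reverse_complement=False)) == 0
        assert bitap_count(probe, read, MatchParams(k=1, search_reverse_complement=False)) == 1

    def test_reverse_complement_found_by_default(self):
        probe = make_probe(PROBE28)
        read = "TT" + revcomp(PROBE28) + "GG"
        assert bitap_count(probe, read, MatchParams(k=0)) == 1
        assert bitap_count(probe, read, MatchParams(k=0, search_reverse_complement=False)) == 0

    def test_n_in_read_never_matches(self):
        probe = make_probe(PROBE28)
        read = PROBE28.replace("A", "N", 1)
        assert bitap_count(probe, read, MatchParams(k=0)) == 0
        # but an N can be consumed as one of the k mismatches
        assert bitap_count(probe, read, MatchParams(k=1, search_reverse_complement=False)) == 1

    def test_k_too_large_rejected(self):
        with pytest.raises(ValidationError):
            bitap_count(make_probe("ACGTAC"), "ACGTAC", MatchParams(k=6))

    def test_edit_model_finds_indel(self):
        probe = make_probe(PROBE28)
        deleted = PROBE28[:10] + PROBE28[11:]
        params = MatchParams(k=1, distance_model="edit", search_reverse_complement=False)
        assert bitap_count(probe, deleted, params) >= 1
        assert bitap_count(probe, deleted, MatchParams(k=1, search_reverse_complement=False)) == 0

    def test_min_flank_filters_edge_hits(self):
        probe = make_probe("ACGTAACC")  # L=8, split=4
        read = "ACGTAACC" + "G" * 20
        # junction point sits at read position 4; flank of 5 on the left unavailable
        assert bitap_count(probe, read, MatchParams(k=0, min_flank=5, search_reverse_complement=False)) == 0
        assert bitap_count(probe, read, MatchParams(k=0, min_flank=4, search_reverse_complement=False)) == 1


def random_instance(rng, L, k, plant):
    probe = "".join(rng.choice(list("ACGT"), size=L))
    read = list(rng.choice(list("ACGT"), size=100))
    if plant:
        pos = int(rng.integers(0, 100 - L + 1))
        mutated = list(probe)
        for i in rng.choice(L, size=int(rng.integers(0, k + 1)), replace=False):
            mutated[int(i)] = rng.choice([c for c in "ACGT" if c != mutated[int(i)]])
        read[pos : pos + L] = mutated
    return probe, "".join(read)


class TestOracleEquivalence:
    @pytest.mark.parametrize("L", [8, 16, 28])
    @pytest.mark.parametrize("k", [0, 1, 2])
    def test_hamming_random(self, L, k):
        rng = np.random.default_rng(L * 100 + k)
        for trial in range(60):
            probe, read = random_instance(rng, L, k, plant=trial % 2 == 0)
            assert len(_bitap_hamming(probe, read, k)) == len(hamming_occurrences(probe, read, k))

    @pytest.mark.parametrize("L", [8, 16, 28])
    @pytest.mark.parametrize("k", [0, 1, 2])
    def test_edit_random(self, L, k):
        rng = np.random.default_rng(L * 100 + k + 7)
        for trial in range(60):
            probe, read = random_instance(rng, L, k, plant=trial % 2 == 0)
            assert _bitap_edit(probe, read, k) == edit_occurrences(probe, read, k)

    def test_exact_path_equals_bitap_at_k0(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            probe, read = random_instance(rng, 8, 0, plant=True)
            assert _count_exact(probe, read) == _bitap_hamming(probe, read, 0)
            assert _count_exact(probe, read) == _bitap_edit(probe, read, 0)

    def test_exhaustive_small(self):
        # all reads of length 6 over a two-letter alphabet vs a fixed 4-mer
        from itertools import product

        probe = "ACAC"
        for k in (0, 1):
            for letters in product("AC", repeat=6):
                read = "".join(letters)
                assert len(_bitap_hamming(probe, read, k)) == len(hamming_occurrences(probe, read, k))
                assert _bitap_edit(probe, read, k) == edit_occurrences(probe, read, k)

    @given(read=dna, k=st.integers(min_value=0, max_value=2))
    @settings(max_examples=150, deadline=None)
    def test_hamming_hypothesis(self, read, k):
        probe = "ACGTTGCA"
        assert len(_bitap_hamming(probe, read, k)) == len(hamming_occurrences(probe, read, k))

    @given(read=dna, k=st.integers(min_value=0, max_value=2))
    @settings(max_examples=150, deadline=None)
    def test_edit_hypothesis(self, read, k):
        probe = "ACGTTGCA"
        assert _bitap_edit(probe, read, k) == edit_occurrences(probe, read, k)


class TestProperties:
    @given(read=dna)
    @settings(max_examples=100, deadline=None)
    def test_monotonic_in_k(self, read):
        probe = make_probe("ACGTTGCA")
        counts = [
            bitap_count(probe, read, MatchParams(k=k, search_reverse_complement=False))
            for k in range(3)
        ]
        assert counts == sorted(counts)
        edit_counts = [
            bitap_count(probe, read, MatchParams(k=k, distance_model="edit", search_reverse_complement=False))
            for k in range(3)
        ]
        assert edit_counts == sorted(edit_counts)

    @given(read=dna, k=st.integers(min_value=0, max_value=2))
    @settings(max_examples=100, deadline=None)
    def test_strand_symmetry_per_read(self, read, k):
        probe = make_probe("ACGTTGCA")
        params = MatchParams(k=k)
        assert bitap_count(probe, read, params) == bitap_count(probe, revcomp(read), params)


class TestCountSample:
    def test_zero_reads_all_zero(self):
        probes = [make_probe(PROBE28)]
        assert count_reads(probes, []) == {"P1": 0}

    def test_read_with_probe_twice_counts_once(self):
        probes = [make_probe(PROBE28)]
        read = PROBE28 + "TTTT" + PROBE28
        assert count_reads(probes, [("r1", read)]) == {"P1": 1}

    def test_read_order_and_file_split_invariance(self, tmp_path):
        rng = np.random.default_rng(5)
        reads = []
        for i in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            if i % 5 == 0:
                seq = seq[:10] + PROBE28 + seq[38:]
            reads.append((f"r{i}", seq))
        probes = [make_probe(PROBE28)]
        one = tmp_path / "all.fastq"
        formats_io.write_fastq(reads, one)
        a1, a2 = tmp_path / "a1.fastq", tmp_path / "a2.fastq"
        formats_io.write_fastq(reads[:20], a1)
        formats_io.write_fastq(list(reversed(reads[20:])), a2)
        assert count_sample(probes, [one]) == count_sample(probes, [a1, a2])

    def test_cohort_matches_truth_and_thread_invariant(self, sim):
        probes, _ = build_probes(sim.calls)
        sheet = sim.sample_sheet
        serial = count_cohort(probes, sheet)
        threaded = count_cohort(probes, sheet, threads=3)
        assert serial.counts.equals(threaded.counts)
        realized = sim.truth.realized
        assert serial.counts[realized.columns].loc[realized.index].equals(realized)

    def test_duplicate_sample_id_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            SampleSheet(
                [SampleEntry("s", "case", ()), SampleEntry("s", "control", ())]
            )
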