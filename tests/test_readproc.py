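import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dbeprof import (
    MutationProfile,
    Read,
    ReadSet,
    align_read,
    build_pileup,
    merge_pairs,
    merge_readset,
    parse_md,
    sample_reads,
    simulate_mutagenesis,
    substitutions_per_read,
)
from dbeprof.guides import ReferenceAmplicon, revcomp
from dbeprof.readproc import (
    AlignedRead,
    MDParseError,
    md_tag,
    read_fastq_pair,
    read_pileup_text,
    read_sam,
    write_fastq,
    write_pileup_text,
    write_sam,
)
from conftest import make_amplicon, uniform_config
from oracles import gotoh_fit_score, recount_pileup, score_alignment


def _mk_read(seq, qual=None, rid="r"):
    return Read(rid, seq, qual if qual is not None else "I" * len(seq))


class TestMergePairs:
    def test_identical_full_overlap(self):
        seq = "ACGTACGTAC" * 10
        r1 = _mk_read(seq)
        r2 = _mk_read(revcomp(seq))
        merged = merge_pairs(r1, r2)
        assert merged.sequence == seq
        assert merged.quality == r1.quality

    def test_layout_arithmetic_250_over_400(self):
        rng = np.random.default_rng(0)
        genome = "".join(rng.choice(list("ACGT"), 400))
        r1 = _mk_read(genome[:250])
        r2 = _mk_read(revcomp(genome[150:]))
        merged = merge_pairs(r1, r2)
        assert len(merged.sequence) == 400
        assert merged.sequence == genome

    def test_quality_consensus_takes_higher(self):
        # single disagreement in a full overlap; r1 base carries Q30, r2 Q15
        seq = "ACGTACGTACGTACGTACGT"
        other = "T" + seq[1:]
        q_hi = chr(33 + 30) * len(seq)
        q_lo = chr(33 + 15) * len(seq)
        merged = merge_pairs(_mk_read(seq, q_hi), _mk_read(revcomp(other), q_lo[::-1]))
        assert merged.sequence == seq
        assert merged.quality[0] == chr(33 + 15)  # min at disagreement
        assert merged.quality[1] == chr(33 + 30)  # max at agreement

    def test_no_admissible_overlap_returns_none(self):
        assert merge_pairs(_mk_read("A" * 30), _mk_read("A" * 30), min_overlap=10) is None
        # (mate revcomps to T*30: every overlap is all-mismatch)

    def test_merge_idempotent_under_full_overlap(self):
        seq = "ACGGATCGATTACAGGCATTGACG"
        merged = merge_pairs(_mk_read(seq), _mk_read(revcomp(seq)))
        again = merge_pairs(merged, _mk_read(revcomp(merged.sequence), merged.quality[::-1]))
        assert again.sequence == merged.sequence and again.quality == merged.quality

    def test_unmerged_counted_and_dropped(self):
        rs = ReadSet(pairs=[(_mk_read("A" * 30), _mk_read("A" * 30))])
        merged, unmerged = merge_readset(rs)
        assert unmerged == 1 and len(merged.singles) == 0


@pytest.fixture(scope="module")
def ref():
    return make_amplicon(seed=19, length=120, pam3=100)[0]


@pytest.fixture(scope="module")
def ref100():
    return make_amplicon(seed=23, length=100, pam3=80)[0]


class TestAlignRead:
    def test_exact_substring(self, ref):
        a = align_read(ref.sequence[20:80], ref, fastpath=False)
        assert a.mismatches == [] and a.indels == []
        assert a.ref_start == 20 and a.aligned

    def test_single_substitution(self, ref):
        read = list(ref.sequence[10:70])
        read[25] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[25]]
        a = align_read("".join(read), ref, fastpath=False)
        assert len(a.mismatches) == 1
        assert a.mismatches[0][0] == 35

    def test_empty_read_errors(self, ref):
        with pytest.raises(ValueError):
            align_read("", ref)

    def test_low_identity_flagged_not_raised(self, ref):
        a = align_read("A" * 60 if ref.sequence[:60].count("A") < 45 else "C" * 60,
                       ref, fastpath=False)
        assert a.aligned is False

    def test_fastpath_matches_dp_on_full_length_reads(self, ref):
        read = list(ref.sequence)
        read[30] = {"A": "G", "C": "T", "G": "A", "T": "C"}[read[30]]
        fast = align_read("".join(read), ref, fastpath=True)
        slow = align_read("".join(read), ref, fastpath=False)
        assert fast.mismatches == slow.mismatches
        assert fast.score == slow.score

    @pytest.mark.parametrize("seed", range(12))
    def test_score_equals_bruteforce_dp(self, seed):
        """Vectorised Gotoh equals a naive full-matrix DP on small instances."""
        rng = np.random.default_rng(seed)
        ref_seq = "".join(rng.choice(list("ACGT"), 50))
        ref = ReferenceAmplicon("r", ref_seq)
        start = int(rng.integers(0, 10))
        end = int(rng.integers(40, 51))
        read = list(ref_seq[start:end])
        # random edits: substitutions, a deletion and/or an insertion
        for _ in range(int(rng.integers(0, 3))):
            i = int(rng.integers(0, len(read)))
            read[i] = "ACGT"[int(rng.integers(4))]
        if rng.random() < 0.5 and len(read) > 12:
            del read[int(rng.integers(3, len(read) - 3))]
        if rng.random() < 0.5 and len(read) > 12:
            read.insert(int(rng.integers(3, len(read) - 3)), "ACGT"[int(rng.integers(4))])
        read = "".join(read)
        a = align_read(read, ref, fastpath=False)
        assert a.score == gotoh_fit_score(read, ref_seq)
        # the reported path must itself attain the optimal score
        assert score_alignment(a, ref_seq) == a.score
        assert a.query_length == len(read)

    def test_single_deletion_recovered(self, ref):
        read = ref.sequence[5:40] + ref.sequence[41:80]
        a = align_read(read, ref, fastpath=False)
        assert sum(1 for _, kind, _ in a.indels if kind == "del") == 1
        assert a.score == gotoh_fit_score(read, ref.sequence)


class TestPileup:
    def test_perfect_reads(self, ref100):
        alignments = [align_read(ref100.sequence, ref100) for _ in range(100)]
        cols = build_pileup(alignments, ref100)
        assert all(c.depth_clean == 100 and not c.alt_counts for c in cols)

    def test_known_substitution_counts(self, ref100):
        ref_base = ref100.sequence[17]
        alt = "T" if ref_base != "T" else "A"
        mutated = ref100.sequence[:17] + alt + ref100.sequence[18:]
        alignments = [align_read(ref100.sequence, ref100) for _ in range(95)]
        alignments += [align_read(mutated, ref100) for _ in range(5)]
        cols = build_pileup(alignments, ref100)
        assert cols[17].alt_counts == {alt: 5}
        assert cols[17].depth_clean == 100

    def test_randomized_recount_matches_oracle(self, amplicon):
        """Pileup counts equal a brute-force per-read recount (200 reads)."""
        ref, guide = amplicon
        config = uniform_config(ref, guide, base_rate_r=2e-3, indel_rate=5e-4,
                                n_genomes=200, seed=31)
        pool = simulate_mutagenesis(config)
        reads = sample_reads(pool, 200, 250, True, 0.002, seed=31)
        merged, _ = merge_readset(reads)
        alignments = [align_read(r, ref) for r in merged.singles]
        cols = build_pileup(alignments, ref)
        depth, alt, indel = recount_pileup(alignments, len(ref))
        for c in cols:
            assert c.depth_clean == depth[c.ref_pos]
            assert c.alt_counts == alt[c.ref_pos]
            assert c.indel_count == indel[c.ref_pos]

    def test_out_of_bounds_alignment_errors(self, ref100):
        a = AlignedRead("bad", 60, [("M", 50)], [], [], query_sequence="A" * 50)
        with pytest.raises(ValueError):
            build_pileup([a], ref100)

    def test_deletion_column_excluded_from_clean_depth(self, ref100):
        read = ref100.sequence[:40] + ref100.sequence[41:]
        alignments = [align_read(ref100.sequence, ref100) for _ in range(9)]
        alignments.append(align_read(read, ref100, fastpath=False))
        cols = build_pileup(alignments, ref100)
        del_col = next(c for c in cols if c.indel_count)
        assert del_col.depth_clean == 9 and del_col.indel_count == 1


class TestPerReadCounts:
    def test_trace_examples(self, amplicon):
        ref, _ = amplicon
        perfect = align_read(ref.sequence[:100], ref, fastpath=False)
        assert substitutions_per_read(perfect) == 0
        one = list(ref.sequence[:100])
        one[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[one[10]]
        assert substitutions_per_read(align_read("".join(one), ref, fastpath=False)) == 1
        # deletion plus two substitutions counts 2, not 3
        two = list(ref.sequence[:60]) + list(ref.sequence[61:100])
        two[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[two[5]]
        two[20] = {"A": "G", "C": "T", "G": "A", "T": "C"}[two[20]]
        a = align_read("".join(two), ref, fastpath=False)
        assert sum(1 for _, k, _ in a.indels if k == "del") == 1
        assert substitutions_per_read(a) == 2

    def test_unaligned_read_errors(self):
        a = AlignedRead("x", 0, [("M", 5)], [], [], aligned=False)
        with pytest.raises(ValueError):
            substitutions_per_read(a)


class TestParseMD:
    @pytest.mark.parametrize(
        "md,cigar,expected",
        [
            ("250", "250M", (0, 0)),
            ("10A239", "250M", (1, 0)),
            ("5^AC3T1", "5M2D5M", (1, 2)),
            ("0A4", "5M", (1, 0)),
        ],
    )
    def test_grammar(self, md, cigar, expected):
        assert parse_md(md, cigar) == expected

    @pytest.mark.parametrize(
        "md,cigar",
        [
            ("250", "240M"),          # aligned length mismatch
            ("5^AC3", "5M3D3M"),      # deletion length mismatch
            ("5x3", "9M"),            # illegal character
        ],
    )
    def test_inconsistencies_raise(self, md, cigar):
        with pytest.raises(MDParseError):
            parse_md(md, cigar)

    def test_internal_counts_match_md_on_sam_roundtrip(self, tmp_path, amplicon):
        """substitutions_per_read == parse_md on the SAM serialisation, per read."""
        ref, guide = amplicon
        config = uniform_config(ref, guide, base_rate_r=2e-3, indel_rate=5e-4,
                                n_genomes=100, seed=37)
        pool = simulate_mutagenesis(config)
        reads = sample_reads(pool, 120, 250, True, 0.001, seed=37)
        merged, _ = merge_readset(reads)
        alignments = [a for r in merged.singles
                      if (a := align_read(r, ref)).aligned]
        sam_path = tmp_path / "reads.sam"
        write_sam(alignments, ref, sam_path)
        back = read_sam(sam_path, ref)
        assert len(back) == len(alignments)
        for orig, rec in zip(alignments, back):
            subs, dels = parse_md(md_tag(orig, ref), orig.cigar())
            assert subs == substitutions_per_read(orig)
            assert rec.mismatches == orig.mismatches
            assert dels == sum(n for _, k, n in orig.indels if k == "del")

    @given(st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_md_roundtrip_random_edits(self, seed):
        """md_tag/parse_md agree with the alignment's own mismatch/deletion lists."""
        rng = np.random.default_rng(seed)
        ref_seq = "".join(rng.choice(list("ACGT"), 60))
        ref = ReferenceAmplicon("r", ref_seq)
        read = list(ref_seq[5:55])
        for _ in range(int(rng.integers(0, 4))):
            i = int(rng.integers(0, len(read)))
            read[i] = "ACGT"[int(rng.integers(4))]
        if rng.random() < 0.4:
            del read[int(rng.integers(5, len(read) - 5))]
        a = align_read("".join(read), ref, fastpath=False)
        subs, dels = parse_md(md_tag(a, ref), a.cigar())
        assert subs == len(a.mismatches)
        assert dels == sum(n for _, k, n in a.indels if k == "del")


class TestRoundTripAgainstTruth:
    def test_pileup_equals_ground_truth_tallies(self, amplicon):
        """Error-free, one read per genome: pileup == simulator ground truth."""
        ref, guide = amplicon
        config = uniform_config(ref, guide, base_rate_r=2e-3, n_genomes=300, seed=41)
        pool = simulate_mutagenesis(config)
        reads = [Read(f"g{i}", s, "I" * len(s)) for i, s in enumerate(pool.sequences)]
        alignments = [align_read(r, ref) for r in reads]
        cols = build_pileup(alignments, ref)
        truth: dict[tuple[int, str], int] = {}
        for muts in pool.per_genome_mutations:
            for pos, _, alt in muts:
                truth[(pos, alt)] = truth.get((pos, alt), 0) + 1
        observed = {
            (c.ref_pos, b): k for c in cols for b, k in c.alt_counts.items()
        }
        assert observed == truth


class TestTextIO:
    def test_fastq_roundtrip(self, tmp_path, amplicon):
        ref, guide = amplicon
        pool = simulate_mutagenesis(uniform_config(ref, guide, n_genomes=10))
        rs = sample_reads(pool, 8, 250, True, 0.001, seed=5)
        p1, p2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        write_fastq(rs, p1, p2)
        back = read_fastq_pair(p1, p2)
        assert [(a.sequence, b.sequence) for a, b in back.pairs] == [
            (a.sequence, b.sequence) for a, b in rs.pairs
        ]

    def test_pileup_text_roundtrip(self, amplicon):
        ref, guide = amplicon
        config = uniform_config(ref, guide, base_rate_r=2e-3, indel_rate=1e-3,
                                n_genomes=150, seed=43)
        pool = simulate_mutagenesis(config)
        reads = [Read(f"g{i}", s, "I" * len(s)) for i, s in enumerate(pool.sequences)]
        alignments = [align_read(r, ref) for r in reads]
        cols = build_pileup(alignments, ref)
        import os
        import tempfile

        with tempfile.TemporaryDirectory() as d:
            path = os.path.join(d, "pile.txt")
            write_pileup_text(cols, ref.id, path)
            back = read_pileup_text(path)
        for orig, rec in zip(cols, back):
            assert rec.depth_clean == orig.depth_clean
            assert rec.alt_counts == orig.alt_counts
            assert rec.indel_count == orig.indel_count
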