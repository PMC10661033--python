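"""Read processing: pair merging, glocal alignment, pileup, MD tags.

These are in-package re-implementations of the merge/align/pileup stages
usually delegated to BBMerge, bwa mem and samtools mpileup.  Amplicons are
short (hundreds of bp) and read counts moderate, so an exact
dynamic-programming glocal alignment (read global, reference local, affine
gaps) is affordable and removes the heuristics of a general-purpose mapper.

Coordinates are 0-based half-open internally; SAM I/O converts to and from
1-based.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .guides import ReferenceAmplicon, revcomp

NEG = -(10**7)  # -infinity for integer DP


@dataclass
class Read:
    """A sequencing read; quality is Phred+33, same length as the sequence."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.id}: invalid bases {sorted(bad)}")
        self.sequence = self.sequence.upper()


@dataclass
class ReadSet:
    """Single (merged) reads plus mate pairs awaiting merging."""

    singles: list[Read] = field(default_factory=list)
    pairs: list[tuple[Read, Read]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.singles) + len(self.pairs)


@dataclass(frozen=True)
class Scoring:
    """Affine alignment scores; a gap of length L costs open + (L-1)*extend."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -4
    gap_extend: int = -1


@dataclass
class AlignedRead:
    """A read aligned to the reference.

    ``ops`` is an ordered run-length list over {'M' match, 'X' substitution,
    'I' insertion, 'D' deletion}; reads recovered from SAM may carry plain
    'M' runs covering both matches and substitutions — the ``mismatches``
    list is authoritative for substitution calls.  Read bases called ``N``
    are listed in ``ambiguous`` and excluded from both mismatch and depth
    accounting downstream.
    """

    query_id: str
    ref_start: int
    ops: list[tuple[str, int]]
    mismatches: list[tuple[int, str, str]]  # (ref_pos, ref_base, alt_base)
    indels: list[tuple[int, str, int]]      # (ref_pos, 'ins'|'del', length)
    ambiguous: list[int] = field(default_factory=list)
    aligned: bool = True
    score: int = 0
    query_sequence: str = ""
    query_quality: str = ""

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.ops if op in "MXD")

    @property
    def query_length(self) -> int:
        return sum(n for op, n in self.ops if op in "MXI")

    def cigar(self) -> str:
        out = []
        for op, n in self.ops:
            c = "M" if op in "MX" else op
            if out and out[-1][0] == c:
                out[-1][1] += n
            else:
                out.append([c, n])
        return "".join(f"{n}{c}" for c, n in out)


# ---------------------------------------------------------------------------
# Pair merging


def _overlap_consensus(a1, q1, a2, q2):
    agree = a1 == a2
    take1 = q1 >= q2
    base = np.where(agree, a1, np.where(take1, a1, a2))
    qual = np.where(agree, np.maximum(q1, q2), np.minimum(q1, q2))
    return base, qual


def merge_pairs(
    r1: Read,
    r2: Read,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> Read | None:
    """Merge a mate pair into a single read via their 3' overlap.

    ``r2`` is reverse-complemented, then every overlap length from
    ``min_overlap`` up to the shorter read is scored; the overlap
    maximizing the number of agreeing bases subject to a mismatch fraction
    cap wins (ties go to the longer overlap).  Disagreements take the
    higher-quality base; quality is the per-position max where the mates
    agree and the min where they disagree.  Returns ``None`` when no
    admissible overlap exists (caller counts and drops).
    """
    s1, q1s = r1.sequence, r1.quality
    s2, q2s = revcomp(r2.sequence), r2.quality[::-1]
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    qa1 = np.frombuffer(q1s.encode(), dtype=np.uint8)
    qa2 = np.frombuffer(q2s.encode(), dtype=np.uint8)
    max_ov = min(len(a1), len(a2))
    best: tuple[int, int] | None = None  # (matches, overlap)
    for ov in range(max_ov, max(min_overlap, 1) - 1, -1):
        if best is not None and best[0] >= ov:
            break  # no shorter overlap can contain more matches
        mism = int(np.count_nonzero(a1[len(a1) - ov :] != a2[:ov]))
        if mism / ov <= max_mismatch_frac:
            matches = ov - mism
            if best is None or matches > best[0]:
                best = (matches, ov)
    if best is None:
        return None
    ov = best[1]
    base, qual = _overlap_consensus(
        a1[len(a1) - ov :], qa1[len(qa1) - ov :], a2[:ov], qa2[:ov]
    )
    merged_seq = s1[: len(a1) - ov] + base.tobytes().decode() + s2[ov:]
    merged_qual = q1s[: len(a1) - ov] + qual.tobytes().decode() + q2s[ov:]
    merged_id = r1.id[:-2] if r1.id.endswith("/1") else r1.id
    return Read(merged_id, merged_seq, merged_qual)


def merge_readset(
    readset: ReadSet, min_overlap: int = 10, max_mismatch_frac: float = 0.1
) -> tuple[ReadSet, int]:
    """Merge every pair in a ReadSet; returns (merged set, unmerged count)."""
    singles = list(readset.singles)
    unmerged = 0
    for r1, r2 in readset.pairs:
        m = merge_pairs(r1, r2, min_overlap, max_mismatch_frac)
        if m is None:
            unmerged += 1
        else:
            singles.append(m)
    return ReadSet(singles=singles, pairs=[]), unmerged


# ---------------------------------------------------------------------------
# Glocal (fitting) alignment: read global, reference local


def _ops_from_path(path, read, ref, ref_start, query_id, quality, score, min_identity):
    """Convert a traceback path of per-column ops into an AlignedRead."""
    ops: list[tuple[str, int]] = []
    mismatches: list[tuple[int, str, str]] = []
    ambiguous: list[int] = []
    indels: list[tuple[int, str, int]] = []
    i = 0  # read cursor
    j = ref_start  # reference cursor
    matches = 0
    k = 0
    while k < len(path):
        op = path[k]
        run = 1
        while k + run < len(path) and path[k + run] == op:
            run += 1
        if op == "M":
            for off in range(run):
                rb, qb = ref[j + off], read[i + off]
                if qb == "N":
                    ambiguous.append(j + off)
                elif qb != rb:
                    mismatches.append((j + off, rb, qb))
                else:
                    matches += 1
            i += run
            j += run
            ops.append(("M", run))
        elif op == "D":
            indels.append((j, "del", run))
            ops.append(("D", run))
            j += run
        else:  # 'I'
            col = j - 1 if j > ref_start else j
            indels.append((col, "ins", run))
            ops.append(("I", run))
            i += run
        k += run
    # split M runs into M/X for exactness of the op list
    refined: list[tuple[str, int]] = []
    i = 0
    j = ref_start
    mism_set = {p for p, _, _ in mismatches}
    for op, run in ops:
        if op != "M":
            refined.append((op, run))
            if op == "I":
                i += run
            else:
                j += run
            continue
        start = 0
        for off in range(run):
            cur = "X" if (j + off) in mism_set else "M"
            if off == 0:
                cur_run, cur_op = 1, cur
                continue
            if cur == cur_op:
                cur_run += 1
            else:
                refined.append((cur_op, cur_run))
                cur_op, cur_run = cur, 1
        refined.append((cur_op, cur_run))
        i += run
        j += run
    total_cols = sum(n for _, n in refined)
    identity = matches / total_cols if total_cols else 0.0
    return AlignedRead(
        query_id=query_id,
        ref_start=ref_start,
        ops=refined,
        mismatches=mismatches,
        indels=indels,
        ambiguous=ambiguous,
        aligned=identity >= min_identity,
        score=score,
        query_sequence=read,
        query_quality=quality,
    )


def align_read(
    read: str | Read,
    reference: ReferenceAmplicon,
    scoring: Scoring = Scoring(),
    min_identity: float = 0.8,
    fastpath: bool = True,
) -> AlignedRead:
    """Optimal glocal alignment of a read against the amplicon.

    The read is aligned end-to-end; the reference may be entered and left
    anywhere (no penalty for unaligned reference flanks).  Affine gap
    scoring via the Gotoh recurrence, integer scores, deterministic
    tie-breaking (diagonal > deletion > insertion; leftmost end point).
    Reads whose alignment identity falls below ``min_identity`` are
    returned with ``aligned=False`` rather than raising.

    ``fastpath`` short-circuits reference-length reads that are >=98%
    identical by direct comparison into an ungapped alignment — the common
    case for merged amplicon reads.
    """
    if isinstance(read, Read):
        query_id, seq, quality = read.id, read.sequence, read.quality
    else:
        query_id, seq, quality = "read", read.upper(), ""
    if not seq:
        raise ValueError("cannot align an empty read")
    ref = reference.sequence
    n, m = len(seq), len(ref)

    if fastpath and n == m:
        a = np.frombuffer(seq.encode(), dtype=np.uint8)
        b = np.frombuffer(ref.encode(), dtype=np.uint8)
        ndiff = int(np.count_nonzero(a != b))
        if ndiff <= max(2, int(0.02 * n)):
            path = ["M"] * n
            score = (n - ndiff) * scoring.match + ndiff * scoring.mismatch
            return _ops_from_path(path, seq, ref, 0, query_id, quality, score, min_identity)

    go, ge = scoring.gap_open, scoring.gap_extend
    enc = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    q = np.array([enc[c] for c in seq], dtype=np.int8)
    r = np.array([enc[c] for c in ref], dtype=np.int8)

    H = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in read (D)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in ref (I)
    H[0, :] = 0
    ks = np.arange(m)
    for i in range(1, n + 1):
        F[i] = np.maximum(H[i - 1] + go, F[i - 1] + ge)
        # N never scores as a match
        sub = np.where((q[i - 1] == r) & (q[i - 1] != 4), scoring.match, scoring.mismatch)
        diag = H[i - 1, :-1] + sub
        cand = np.maximum(diag, F[i, 1:])
        hn = np.empty(m + 1, dtype=np.int32)
        hn[0] = F[i, 0]
        hn[1:] = cand
        t = hn[:-1] - ge * ks
        cm = np.maximum.accumulate(t)
        E[i, 1:] = go + ge * ks + cm
        H[i, 0] = hn[0]
        H[i, 1:] = np.maximum(cand, E[i, 1:])

    end_j = int(np.argmax(H[n]))
    score = int(H[n, end_j])

    # traceback
    path: list[str] = []
    i, j, state = n, end_j, "H"
    while i > 0:
        if state == "H":
            sub = (
                scoring.match
                if (j > 0 and q[i - 1] == r[j - 1] and q[i - 1] != 4)
                else scoring.mismatch
            )
            if j > 0 and H[i, j] == H[i - 1, j - 1] + sub:
                path.append("M")
                i -= 1
                j -= 1
            elif j > 0 and H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            path.append("D")
            j -= 1
            if not (j > 0 and E[i, j + 1] == E[i, j] + ge):
                state = "H"
        else:  # F
            path.append("I")
            i -= 1
            if not (i > 0 and F[i + 1, j] == F[i, j] + ge):
                state = "H"
    path.reverse()
    return _ops_from_path(path, seq, ref, j, query_id, quality, score, min_identity)


# ---------------------------------------------------------------------------
# Pileup


@dataclass
class PileupColumn:
    """Per-position tally backing the substitution-rate statistic.

    ``depth_clean`` counts reads covering the column with neither an
    insertion nor a deletion at it (and a called base, not N);
    ``alt_counts`` tallies substitution bases among those reads;
    ``indel_count`` counts reads with an insertion or deletion at the
    column.
    """

    ref_pos: int
    ref_base: str
    depth_clean: int
    alt_counts: dict[str, int]
    indel_count: int

    def __post_init__(self) -> None:
        if self.depth_clean < 0 or self.indel_count < 0 or any(
            v < 0 for v in self.alt_counts.values()
        ):
            raise ValueError("negative pileup counts")
        if sum(self.alt_counts.values()) > self.depth_clean:
            raise ValueError("alt counts exceed clean depth")


def build_pileup(
    alignments: list[AlignedRead], reference: ReferenceAmplicon
) -> list[PileupColumn]:
    """Compile per-position base counts from aligned reads.

    Reads flagged unaligned are skipped.  A read contributes to
    ``depth_clean`` at every column it covers through match/substitution
    ops, except columns where it carries an indel (counted in
    ``indel_count`` instead) or an N base (excluded entirely).
    """
    L = len(reference)
    depth = np.zeros(L + 1, dtype=np.int64)  # diff array
    alt = np.zeros((4, L), dtype=np.int64)
    indel = np.zeros(L, dtype=np.int64)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for a in alignments:
        if not a.aligned:
            continue
        end = a.ref_start + a.ref_span
        if a.ref_start < 0 or end > L:
            raise ValueError(f"alignment of {a.query_id} beyond reference bounds")
        depth[a.ref_start] += 1
        depth[end] -= 1
        for pos, kind, length in a.indels:
            if kind == "del":
                for c in range(pos, pos + length):
                    depth[c] -= 1
                    depth[c + 1] += 1
                    indel[c] += 1
            else:  # insertion: assigned to the column left of the inserted bases
                depth[pos] -= 1
                depth[pos + 1] += 1
                indel[pos] += 1
        for pos in a.ambiguous:
            depth[pos] -= 1
            depth[pos + 1] += 1
        for pos, _ref_base, alt_base in a.mismatches:
            alt[base_idx[alt_base], pos] += 1
    clean = np.cumsum(depth[:-1])
    cols = []
    for p in range(L):
        counts = {b: int(alt[i, p]) for b, i in base_idx.items() if alt[i, p]}
        cols.append(
            PileupColumn(
                ref_pos=p,
                ref_base=reference.sequence[p],
                depth_clean=int(clean[p]),
                alt_counts=counts,
                indel_count=int(indel[p]),
            )
        )
    return cols


def substitutions_per_read(a: AlignedRead) -> int:
    """Number of substitutions carried by one aligned read."""
    if not a.aligned:
        raise ValueError(f"read {a.query_id} is unaligned")
    return len(a.mismatches)


# ---------------------------------------------------------------------------
# MD tags


class MDParseError(ValueError):
    pass


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_MD_RE = re.compile(r"(\d+)|(\^[A-Z]+)|([A-Z])")


def parse_md(md: str, cigar: str) -> tuple[int, int]:
    """Count substitutions and deleted bases from an MD tag.

    Returns ``(substitution_count, deletion_length)``: single mismatch
    letters outside ``^``-prefixed runs are substitutions; bases inside
    ``^`` runs are deletions.  The MD string is cross-checked against the
    CIGAR (aligned match length and deletion length must agree); a
    mismatch raises :class:`MDParseError` naming the offset.
    """
    cig_m = cig_d = 0
    pos = 0
    for num, op in _CIGAR_RE.findall(cigar):
        if op in "M=X":
            cig_m += int(num)
        elif op == "D":
            cig_d += int(num)
        pos += len(num) + 1
    if pos != len(cigar) or not cigar:
        raise MDParseError(f"invalid CIGAR {cigar!r}")

    subs = 0
    del_len = 0
    md_m = 0
    offset = 0
    expect_number = True
    for m in _MD_RE.finditer(md):
        if m.start() != offset:
            raise MDParseError(f"unparseable MD at offset {offset}")
        if m.group(1) is not None:
            md_m += int(m.group(1))
            expect_number = False
        elif m.group(2) is not None:
            if expect_number:
                raise MDParseError(f"MD deletion without preceding number at offset {offset}")
            del_len += len(m.group(2)) - 1
            expect_number = True
        else:
            subs += 1
            md_m += 1
            expect_number = False
        offset = m.end()
    if offset != len(md):
        raise MDParseError(f"unparseable MD at offset {offset}")
    if md_m != cig_m:
        raise MDParseError(
            f"MD aligned length {md_m} != CIGAR aligned length {cig_m} (MD offset {offset})"
        )
    if del_len != cig_d:
        raise MDParseError(
            f"MD deletion length {del_len} != CIGAR deletion length {cig_d}"
        )
    return subs, del_len


def md_tag(a: AlignedRead, reference: ReferenceAmplicon) -> str:
    """Generate the MD tag for an internal alignment."""
    out: list[str] = []
    run = 0
    j = a.ref_start
    for op, n in a.ops:
        if op == "M":
            run += n
            j += n
        elif op == "X":
            for _ in range(n):
                out.append(str(run))
                out.append(reference.sequence[j])
                run = 0
                j += 1
        elif op == "D":
            out.append(str(run))
            out.append("^" + reference.sequence[j : j + n])
            run = 0
            j += n
        # insertions do not appear in MD
    out.append(str(run))
    return "".join(out)


# ---------------------------------------------------------------------------
# SAM / FASTA / FASTQ / pileup-text I/O


def write_sam(
    alignments: list[AlignedRead], reference: ReferenceAmplicon, path
) -> None:
    """Write aligned reads as a minimal valid SAM file with MD and NM tags."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{reference.id}\tLN:{len(reference)}\n")
        for a in alignments:
            if not a.aligned:
                continue
            nm = len(a.mismatches) + sum(length for _, _, length in a.indels)
            qual = a.query_quality if a.query_quality else "*"
            fh.write(
                "\t".join(
                    [
                        a.query_id.replace(" ", "_"),
                        "0",
                        reference.id,
                        str(a.ref_start + 1),
                        "60",
                        a.cigar(),
                        "*",
                        "0",
                        "0",
                        a.query_sequence or "*",
                        qual,
                        f"NM:i:{nm}",
                        f"MD:Z:{md_tag(a, reference)}",
                    ]
                )
                + "\n"
            )


def read_sam(path, reference: ReferenceAmplicon | None = None) -> list[AlignedRead]:
    """Read mapped SAM records (CIGAR + MD required for mismatch calls)."""
    import pysam

    cigar_ops = {0: "M", 1: "I", 2: "D", 7: "M", 8: "X"}
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            ops: list[tuple[str, int]] = []
            indels: list[tuple[int, str, int]] = []
            j = rec.reference_start
            started = False
            for code, n in rec.cigartuples:
                if code in (4, 5):  # soft/hard clip: treat as unsupported flanks
                    raise ValueError("clipped alignments are not supported")
                op = cigar_ops.get(code)
                if op is None:
                    raise ValueError(f"unsupported CIGAR op code {code}")
                ops.append((op, n))
                if op == "D":
                    indels.append((j, "del", n))
                    j += n
                elif op == "I":
                    col = j - 1 if started else j
                    indels.append((col, "ins", n))
                else:
                    j += n
                    started = True
            mismatches: list[tuple[int, str, str]] = []
            ambiguous: list[int] = []
            qseq = rec.query_sequence or ""
            for qpos, rpos, ref_base in rec.get_aligned_pairs(with_seq=True):
                if qpos is None or rpos is None or ref_base is None:
                    continue
                qb = qseq[qpos].upper()
                if qb == "N":
                    ambiguous.append(rpos)
                elif ref_base.islower():
                    mismatches.append((rpos, ref_base.upper(), qb))
            qual = (
                "".join(chr(33 + q) for q in rec.query_qualities)
                if rec.query_qualities is not None
                else ""
            )
            out.append(
                AlignedRead(
                    query_id=rec.query_name,
                    ref_start=rec.reference_start,
                    ops=ops,
                    mismatches=mismatches,
                    indels=indels,
                    ambiguous=ambiguous,
                    aligned=True,
                    score=0,
                    query_sequence=qseq,
                    query_quality=qual,
                )
            )
    return out


def read_fasta(path) -> ReferenceAmplicon:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceAmplicon(id=rec.id, sequence=str(rec.seq))


def read_fastq(path) -> ReadSet:
    singles = [
        Read(rec.id, str(rec.seq), "".join(chr(33 + q) for q in rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]
    return ReadSet(singles=singles)


def read_fastq_pair(path1, path2) -> ReadSet:
    s1, s2 = read_fastq(path1).singles, read_fastq(path2).singles
    if len(s1) != len(s2):
        raise ValueError("mate files differ in read count")
    return ReadSet(pairs=list(zip(s1, s2)))


def write_fastq(readset: ReadSet, path, path2=None) -> None:
    """Write singles to ``path``; pairs split across ``path`` and ``path2``."""
    if readset.pairs and path2 is None:
        raise ValueError("paired reads need two output paths")
    with open(path, "w") as fh:
        for r in readset.singles:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
        if readset.pairs:
            for r1, _ in readset.pairs:
                fh.write(f"@{r1.id}\n{r1.sequence}\n+\n{r1.quality}\n")
    if readset.pairs:
        with open(path2, "w") as fh:
            for _, r2 in readset.pairs:
                fh.write(f"@{r2.id}\n{r2.sequence}\n+\n{r2.quality}\n")


def write_pileup_text(cols: list[PileupColumn], reference_id: str, path) -> None:
    """samtools-style text pileup (1-based positions; counts re-expanded)."""
    with open(path, "w") as fh:
        for c in cols:
            n_ref = c.depth_clean - sum(c.alt_counts.values())
            bases = "." * n_ref + "".join(b * k for b, k in sorted(c.alt_counts.items()))
            bases += "*" * c.indel_count
            depth = c.depth_clean + c.indel_count
            quals = "I" * depth
            fh.write(
                f"{reference_id}\t{c.ref_pos + 1}\t{c.ref_base}\t{depth}\t{bases}\t{quals}\n"
            )


def read_pileup_text(path) -> list[PileupColumn]:
    """Parse samtools-style text pileup columns (substitutions, *, +/- indels)."""
    cols: list[PileupColumn] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            _, pos1, ref_base, _depth, bases = parts[:5]
            counts: Counter[str] = Counter()
            clean = 0
            indel = 0
            i = 0
            last_was_base = False
            cols_last_alt: str | None = None
            while i < len(bases):
                ch = bases[i]
                if ch == "^":
                    i += 2
                    continue
                if ch == "$":
                    i += 1
                    continue
                if ch in "+-":
                    m = re.match(r"[+-](\d+)", bases[i:])
                    length = int(m.group(1))
                    i += m.end() + length
                    # the preceding read carries an indel at this column
                    if last_was_base:
                        clean -= 1
                        indel += 1
                        if cols_last_alt is not None:
                            counts[cols_last_alt] -= 1
                            if counts[cols_last_alt] == 0:
                                del counts[cols_last_alt]
                    last_was_base = False
                    continue
                cols_last_alt = None
                if ch in ".,":
                    clean += 1
                    last_was_base = True
                elif ch.upper() in "ACGT":
                    clean += 1
                    counts[ch.upper()] += 1
                    cols_last_alt = ch.upper()
                    last_was_base = True
                elif ch == "*":
                    indel += 1
                    last_was_base = False
                else:  # N or other: excluded entirely
                    last_was_base = False
                i += 1
            cols.append(
                PileupColumn(
                    ref_pos=int(pos1) - 1,
                    ref_base=ref_base.upper(),
                    depth_clean=clean,
                    alt_counts=dict(counts),
                    indel_count=indel,
                )
            )
    return cols


def write_per_read_counts_tsv(alignments: list[AlignedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsubstitutions\n")
        for a in alignments:
            if a.aligned:
                fh.write(f"{a.query_id}\t{len(a.mismatches)}\n")
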