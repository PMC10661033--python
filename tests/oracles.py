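"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (triple-loop DP, per-read dict
tallies, exhaustive interval scans) and shares no code with the package.
"""

from __future__ import annotations


def gotoh_fit_score(read: str, ref: str, match=1, mismatch=-1, go=-4, ge=-1) -> int:
    """Optimal glocal (read-global, reference-local) affine-gap score.

    Full-matrix Gotoh recurrence, plain Python.  A gap of length L costs
    go + (L-1)*ge.
    """
    n, m = len(read), len(ref)
    NEG = -(10**9)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        H[0][j] = 0
    for i in range(1, n + 1):
        for j in range(m + 1):
            F[i][j] = max(H[i - 1][j] + go, F[i - 1][j] + ge)
            if j == 0:
                H[i][0] = F[i][0]
                continue
            E[i][j] = max(H[i][j - 1] + go, E[i][j - 1] + ge)
            s = match if (read[i - 1] == ref[j - 1] and read[i - 1] != "N") else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return max(H[n])


def score_alignment(a, ref: str, match=1, mismatch=-1, go=-4, ge=-1) -> int:
    """Re-score an AlignedRead's op list from first principles."""
    score = 0
    i, j = 0, a.ref_start
    read = a.query_sequence
    for op, n in a.ops:
        if op in "MX":
            for k in range(n):
                same = read[i + k] == ref[j + k] and read[i + k] != "N"
                score += match if same else mismatch
            i += n
            j += n
        elif op == "D":
            score += go + (n - 1) * ge
            j += n
        else:  # I
            score += go + (n - 1) * ge
            i += n
    return score


def recount_pileup(alignments, ref_len: int):
    """Per-read loop recount of clean depth, alt counts and indel counts."""
    depth = [0] * ref_len
    alt: list[dict] = [dict() for _ in range(ref_len)]
    indel = [0] * ref_len
    for a in alignments:
        if not a.aligned:
            continue
        covered = set(range(a.ref_start, a.ref_start + a.ref_span))
        bad = set(a.ambiguous)
        for pos, kind, length in a.indels:
            if kind == "del":
                bad.update(range(pos, pos + length))
                for c in range(pos, pos + length):
                    indel[c] += 1
            else:
                bad.add(pos)
                indel[pos] += 1
        for c in covered - bad:
            depth[c] += 1
        mism_bad = {p for p, _, _ in a.mismatches} & bad
        for pos, _rb, ab in a.mismatches:
            if pos not in bad:
                alt[pos][ab] = alt[pos].get(ab, 0) + 1
        assert not mism_bad, "mismatch recorded at an indel column"
    return depth, alt, indel


def shortest_interval(signal, frac):
    """Exhaustive scan for the shortest interval holding >= frac of the mass."""
    total = sum(signal)
    best = None
    n = len(signal)
    for left in range(n):
        acc = 0.0
        for right in range(left, n):
            acc += signal[right]
            if acc >= frac * total - 1e-12:
                width = right - left + 1
                if best is None or width < best:
                    best = width
                break
    return best


STANDARD_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
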