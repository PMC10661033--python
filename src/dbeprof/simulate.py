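"""Forward simulation of guide-directed cytidine-deaminase mutagenesis.

The generative model treats each reference site independently.  A site at
PAM-relative distance ``d`` acquires, per genome and per generation, a
substitution with probability

    q_i = r * w(d_i) * m(context_i) * s(base_i)

where ``r`` is the per-site per-generation base rate, ``w`` a positional
window weight anchored at the PAM 3' end (max over guides when several
guides target the amplicon), ``m`` a sequence-context multiplier reflecting
the deaminase's WRCY / AGCT motif preference (evaluated on the strand where
the C resides), and ``s`` a reference-base multiplier whose A/T entry plays
the role of a background channel.  Over ``g`` (possibly fractional)
generations the cumulative per-site mutated fraction is

    p_i = 1 - (1 - q_i)**g

applied analytically rather than as discrete Bernoulli rounds, because only
cumulative rates are observable and generation counts from OD doublings are
non-integer.  At most one substitution per site per genome; no
back-mutation.  The substituted base is drawn from a per-reference-base
outcome spectrum (C-biased toward C->G by default, mirrored at G sites).

Single-base deletions can be layered on at ``indel_rate`` (default 0) as a
rarity check; they are not a realistic indel model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .guides import GuideDesign, ReferenceAmplicon, revcomp
from .readproc import Read, ReadSet

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: context classes for the motif multiplier
CTX_AGCT = "agct"       # the palindromic AGCT core, most-preferred
CTX_WRCY = "wrcy"       # other WRCY (W=A/T, R=A/G, Y=C/T)
CTX_OTHER = "other"     # non-motif (and all A/T sites)

DEFAULT_MOTIF_MULTIPLIER = {CTX_AGCT: 5.0, CTX_WRCY: 2.0, CTX_OTHER: 1.0}
#: A/T multiplier ~0.013 puts ~1.3% of substitutions at A/T on a ~50% GC
#: amplicon; use calibrate_at_multiplier for an exact composition-aware value.
DEFAULT_BASE_MULTIPLIER = {"CG": 1.0, "AT": 0.013}
DEFAULT_SPECTRUM = {
    "C": {"A": 0.15, "G": 0.50, "T": 0.35},
    "G": {"T": 0.15, "C": 0.50, "A": 0.35},  # complement mirror of the C row
    "A": {"C": 1 / 3, "G": 1 / 3, "T": 1 / 3},
    "T": {"A": 1 / 3, "C": 1 / 3, "G": 1 / 3},
}

WINDOW_SHAPES = ("uniform", "triangular", "gaussian")


def context_class(sequence: str, pos: int) -> str:
    """Motif class of the site, evaluated on the strand carrying the C.

    For a C the 4-mer ``sequence[pos-2 : pos+2]`` is tested against WRCY
    with the C third; for a G the complementary context on the template
    strand is tested.  A/T sites and sequence edges are non-motif.
    """
    base = sequence[pos]
    if base == "C":
        if pos - 2 < 0 or pos + 2 > len(sequence):
            return CTX_OTHER
        ctx = sequence[pos - 2 : pos + 2]
    elif base == "G":
        if pos - 1 < 0 or pos + 3 > len(sequence):
            return CTX_OTHER
        ctx = revcomp(sequence[pos - 1 : pos + 3])
    else:
        return CTX_OTHER
    if ctx == "AGCT":
        return CTX_AGCT
    if ctx[0] in "AT" and ctx[1] in "AG" and ctx[2] == "C" and ctx[3] in "CT":
        return CTX_WRCY
    return CTX_OTHER


@dataclass
class SimulationConfig:
    """All parameters of the deaminase mutagenesis generative model."""

    reference: ReferenceAmplicon
    guides: list[GuideDesign]
    base_rate_r: float = 2.13e-4
    window_halfwidth: int = 50
    window_shape: str = "uniform"
    motif_multiplier: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_MULTIPLIER)
    )
    base_multiplier: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_MULTIPLIER)
    )
    spectrum: dict[str, dict[str, float]] = field(
        default_factory=lambda: {b: dict(row) for b, row in DEFAULT_SPECTRUM.items()}
    )
    generations: float = 20.5
    n_genomes: int = 10_000
    read_length: int = 250
    paired: bool = True
    seq_error_rate: float = 0.001
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_rate_r", "seq_error_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.window_shape not in WINDOW_SHAPES:
            raise ValueError(f"window_shape must be one of {WINDOW_SHAPES}")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.n_genomes < 1 or self.read_length < 1:
            raise ValueError("n_genomes and read_length must be >= 1")
        if self.window_halfwidth < 0:
            raise ValueError("window_halfwidth must be >= 0")
        for base, row in self.spectrum.items():
            total = sum(row.values())
            if any(v < 0 for v in row.values()) or abs(total - 1.0) > 1e-12:
                raise ValueError(f"spectrum row for {base} must be >=0 and sum to 1")
            if base in row:
                raise ValueError(f"spectrum row for {base} may not include {base}")
        for g in self.guides:
            g.validate_against(self.reference)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reference"] = {"id": self.reference.id, "length": len(self.reference)}
        return d


def window_weight(shape: str, halfwidth: int, d: np.ndarray) -> np.ndarray:
    """Positional weight w(d) of PAM-relative distance d, in [0, 1]."""
    d = np.asarray(d, dtype=float)
    if shape == "uniform":
        return (np.abs(d) <= halfwidth).astype(float)
    if shape == "triangular":
        return np.clip(1.0 - np.abs(d) / max(halfwidth, 1), 0.0, None)
    # gaussian: sigma = halfwidth / 2 so ~95% of the weight mass is inside +-W
    sigma = max(halfwidth, 1) / 2.0
    return np.exp(-0.5 * (d / sigma) ** 2)


def site_rates(config: SimulationConfig, at_multiplier: float | None = None) -> np.ndarray:
    """Per-site per-generation substitution probability q_i over the amplicon.

    ``at_multiplier`` overrides the configured A/T base multiplier (used by
    the calibration solver).
    """
    seq = config.reference.sequence
    n = len(seq)
    pos = np.arange(n)
    w = np.zeros(n)
    for g in config.guides:
        w = np.maximum(w, window_weight(config.window_shape, config.window_halfwidth,
                                        g.relative_position(pos)))
    m = np.array([config.motif_multiplier[context_class(seq, i)] for i in range(n)])
    s_at = config.base_multiplier["AT"] if at_multiplier is None else at_multiplier
    s = np.array([config.base_multiplier["CG"] if b in "CG" else s_at for b in seq])
    q = config.base_rate_r * w * m * s
    if np.any(q > 1.0):
        warnings.warn("per-site rate q_i exceeded 1 and was clamped", RuntimeWarning)
        logger.warning("clamped %d sites with q_i > 1", int(np.sum(q > 1.0)))
    return np.clip(q, 0.0, 1.0)


def expected_site_fractions(
    config: SimulationConfig, at_multiplier: float | None = None
) -> np.ndarray:
    """Closed-form expected mutated fraction p_i = 1 - (1 - q_i)^g per site."""
    q = site_rates(config, at_multiplier=at_multiplier)
    return 1.0 - (1.0 - q) ** config.generations


def calibrate_at_multiplier(config: SimulationConfig, target_share: float) -> float:
    """Solve for the A/T base multiplier giving a target expected A/T share.

    The share is the closed-form expected fraction of substitution events
    occurring at A/T reference bases, Σ_AT p_i / Σ p_i, which is monotone
    in the multiplier; solved by bisection.
    """
    from scipy.optimize import brentq

    if not 0.0 < target_share < 1.0:
        raise ValueError("target_share must be in (0, 1)")
    is_at = np.array([b in "AT" for b in config.reference.sequence])

    def share(s_at: float) -> float:
        p = expected_site_fractions(config, at_multiplier=s_at)
        total = p.sum()
        return p[is_at].sum() / total if total > 0 else 0.0

    hi = 1.0
    while share(hi) < target_share:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("target A/T share unreachable")
    return float(brentq(lambda s: share(s) - target_share, 0.0, hi, xtol=1e-12))


@dataclass
class GenomePool:
    """A simulated population of mutated amplicon copies plus ground truth."""

    sequences: list[str]
    per_genome_mutations: list[list[tuple[int, str, str]]]
    per_genome_deletions: list[list[int]]
    config: SimulationConfig

    def __post_init__(self) -> None:
        if len(self.sequences) != self.config.n_genomes:
            raise ValueError("pool size does not match config.n_genomes")

    def total_mutations(self) -> int:
        return sum(len(m) for m in self.per_genome_mutations)


def simulate_mutagenesis(config: SimulationConfig) -> GenomePool:
    """Draw a genome pool under the windowed deaminase model.

    Deterministic for a fixed ``config.seed``: genome draws come from a
    dedicated child stream of the master seed, independent of the stream
    used later for read sampling, so resampling reads never perturbs the
    pool.  Site allocation is vectorised per site (binomial count, then a
    without-replacement draw of genome indices), which is distributionally
    identical to per-genome Bernoulli sweeps.
    """
    ref_seq = config.reference.sequence
    n = config.n_genomes
    p = expected_site_fractions(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])

    muts: dict[int, list[tuple[int, str, str]]] = {}
    for i in np.nonzero(p > 0)[0]:
        k = rng.binomial(n, p[i])
        if k == 0:
            continue
        genomes = rng.choice(n, size=k, replace=False)
        ref_base = ref_seq[i]
        row = config.spectrum[ref_base]
        alts = list(row)
        alt_draws = rng.choice(len(alts), size=k, p=[row[a] for a in alts])
        for gi, ai in zip(genomes.tolist(), alt_draws.tolist()):
            muts.setdefault(gi, []).append((int(i), ref_base, alts[ai]))

    dels: dict[int, list[int]] = {}
    if config.indel_rate > 0:
        for i in range(len(ref_seq)):
            k = rng.binomial(n, config.indel_rate)
            if k == 0:
                continue
            for gi in rng.choice(n, size=k, replace=False).tolist():
                dels.setdefault(gi, []).append(i)

    sequences: list[str] = []
    per_genome_mutations: list[list[tuple[int, str, str]]] = []
    per_genome_deletions: list[list[int]] = []
    for gi in range(n):
        gm = sorted(muts.get(gi, []))
        gd = sorted(dels.get(gi, []))
        if gd:
            # a deleted base cannot also carry a recorded substitution
            gdset = set(gd)
            gm = [m for m in gm if m[0] not in gdset]
        per_genome_mutations.append(gm)
        per_genome_deletions.append(gd)
        if not gm and not gd:
            sequences.append(ref_seq)
            continue
        b = bytearray(ref_seq, "ascii")
        for pos, _ref, alt in gm:
            b[pos] = ord(alt)
        for pos in reversed(gd):
            del b[pos]
        sequences.append(b.decode("ascii"))
    return GenomePool(sequences, per_genome_mutations, per_genome_deletions, config)


# ---------------------------------------------------------------------------
# Read sampling

Q_BASE = chr(33 + 30)   # constant Q30 for called bases
Q_ERR = chr(33 + 15)    # injected sequencing errors are marked Q15

_OTHER_BASES = {b: [x for x in BASES if x != b] for b in BASES}


def _inject_errors(seq: str, qual: str, rate: float, rng) -> tuple[str, str]:
    if rate <= 0:
        return seq, qual
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq, qual
    positions = rng.choice(len(seq), size=k, replace=False)
    s = bytearray(seq, "ascii")
    q = bytearray(qual, "ascii")
    for pos in positions.tolist():
        cur = chr(s[pos])
        if cur not in BASE_INDEX:
            continue
        s[pos] = ord(_OTHER_BASES[cur][rng.integers(3)])
        q[pos] = ord(Q_ERR)
    return s.decode("ascii"), q.decode("ascii")


def sample_reads(
    pool: GenomePool,
    n_reads: int,
    read_length: int,
    paired: bool,
    seq_error_rate: float,
    seed: int,
) -> ReadSet:
    """Sample amplicon reads (or end-anchored pairs) from the genome pool.

    Pairs cover the amplicon from its two ends on opposite strands,
    emulating paired-end amplicon sequencing; the mate is stored 5'->3' on
    the opposite strand as a sequencer would emit it.  Unpaired mode emits
    single reads of ``read_length`` from the amplicon 5' end (a stand-in
    for already-merged reads when ``read_length`` equals the amplicon).
    """
    min_len = min((len(s) for s in pool.sequences), default=0)
    if n_reads and read_length > min_len:
        raise ValueError("read_length exceeds amplicon length")
    if paired and n_reads:
        amplicon_len = len(pool.config.reference)
        if 2 * read_length < amplicon_len:
            raise ValueError("pairs cannot overlap: 2*read_length < amplicon length")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    singles: list[Read] = []
    pairs: list[tuple[Read, Read]] = []
    if n_reads == 0:
        return ReadSet(singles=singles, pairs=pairs)
    genome_idx = rng.integers(0, len(pool.sequences), size=n_reads)
    qual = Q_BASE * read_length
    for ri, gi in enumerate(genome_idx.tolist()):
        g = pool.sequences[gi]
        if paired:
            s1, q1 = _inject_errors(g[:read_length], qual, seq_error_rate, rng)
            s2, q2 = _inject_errors(revcomp(g[-read_length:]), qual, seq_error_rate, rng)
            pairs.append(
                (Read(f"sim_{ri}/1", s1, q1), Read(f"sim_{ri}/2", s2, q2))
            )
        else:
            s, q = _inject_errors(g[:read_length], qual, seq_error_rate, rng)
            singles.append(Read(f"sim_{ri}", s, q))
    return ReadSet(singles=singles, pairs=pairs)


def egfp_shift_fraction(pool: GenomePool, codon_position: int, target_codon: str) -> float:
    """Fraction of genomes whose codon ``codon_position`` equals ``target_codon``.

    The fluorescence-shift correlate: conversion of a wtGFP codon (e.g.
    S65 -> T65) shifts the excitation spectrum, so the fraction of genomes
    carrying the target codon tracks observable editing.  ``codon_position``
    is a 0-based codon index within the reference ORF.  Genomes carrying
    deletions upstream of the codon are frame-shifted and simply compared
    at the reference frame (they will not match).
    """
    ref = pool.config.reference
    orf = ref.orf_offset if ref.orf_offset is not None else 0
    start = orf + 3 * codon_position
    if codon_position < 0 or start + 3 > len(ref):
        raise ValueError("codon_position outside the reference ORF")
    target = target_codon.upper()
    if len(target) != 3:
        raise ValueError("target_codon must be a triplet")
    hits = sum(1 for s in pool.sequences if s[start : start + 3] == target)
    return hits / len(pool.sequences)


# ---------------------------------------------------------------------------
# Serialisation


def write_reference_fasta(ref: ReferenceAmplicon, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ref.id}\n")
        for i in range(0, len(ref.sequence), 70):
            fh.write(ref.sequence[i : i + 70] + "\n")


def write_truth_tsv(pool: GenomePool, path) -> None:
    """Ground-truth substitutions as TSV: genome_id, position (0-based), ref, alt."""
    with open(path, "w") as fh:
        fh.write("genome_id\tposition\tref\talt\n")
        for gi, gm in enumerate(pool.per_genome_mutations):
            for pos, ref_base, alt in gm:
                fh.write(f"{gi}\t{pos}\t{ref_base}\t{alt}\n")


def write_config_yaml(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
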