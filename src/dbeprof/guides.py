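"""Guide-RNA and reference-amplicon bookkeeping.

Everything downstream of read processing is anchored to a guide's PAM, so
this module owns the coordinate conventions:

* The reference amplicon is stored in coding-strand orientation, 0-based.
* ``pam3_pos`` is the position, in coding-strand coordinates, of the
  3'-most base of the NGG PAM *on the protospacer strand*.  For a
  coding-strand protospacer the PAM triplet occupies
  ``[pam3_pos - 2, pam3_pos]``; for a template-strand protospacer it
  occupies ``[pam3_pos, pam3_pos + 2]`` (read 5'->3' on the template,
  i.e. right-to-left on the coding strand).
* Guide names follow the distance-and-side convention used for spacer
  panels around a target codon: ``<t?><distance><L|R>``, e.g. ``t22L``
  for a template-strand guide whose PAM 3' end lies 22 bp left of the
  anchor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq
from Bio.Data.CodonTable import standard_dna_table

DNA_ALPHABET = frozenset("ACGT")
SPACER_LEN = 20

_W = set("AT")
_R = set("AG")
_Y = set("CT")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return str(Seq(seq).reverse_complement())


def gc_content(seq: str) -> float:
    """Fraction of G+C bases in ``seq``; empty input is an error."""
    if not seq:
        raise ValueError("gc_content of an empty sequence is undefined")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


@dataclass
class ReferenceAmplicon:
    """A reference amplicon with optional ORF frame, anchors and features.

    Parameters
    ----------
    id : str
        Sequence identifier (used in FASTA/SAM headers).
    sequence : str
        Uppercase A/C/G/T, coding-strand orientation.
    orf_offset : int, optional
        0-based position of the first base of the first codon, when the
        amplicon carries an open reading frame.
    anchors : dict
        Named 0-based positions, e.g. the first base of a codon of
        interest used for guide naming.
    features : dict
        Named half-open intervals ``[start, end)``, e.g. CDR loops.
    """

    id: str
    sequence: str
    orf_offset: int | None = None
    anchors: dict[str, int] = field(default_factory=dict)
    features: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("reference sequence is empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"reference contains non-ACGT characters: {sorted(bad)}")
        n = len(self.sequence)
        if self.orf_offset is not None and not 0 <= self.orf_offset < n:
            raise ValueError("orf_offset outside reference")
        for name, pos in self.anchors.items():
            if not 0 <= pos < n:
                raise ValueError(f"anchor {name!r} outside reference")
        for name, (s, e) in self.features.items():
            if not (0 <= s < e <= n):
                raise ValueError(f"feature {name!r} outside reference")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GuideDesign:
    """A spacer/PAM/strand record tying a guide to the reference frame."""

    name: str
    spacer: str
    protospacer_strand: str  # "coding" | "template"
    pam3_pos: int

    def __post_init__(self) -> None:
        self.spacer = self.spacer.upper()
        if self.protospacer_strand not in ("coding", "template"):
            raise ValueError("protospacer_strand must be 'coding' or 'template'")
        if len(self.spacer) != SPACER_LEN or set(self.spacer) - DNA_ALPHABET:
            raise ValueError("spacer must be 20 nt of A/C/G/T")

    def pam_triplet(self, ref: ReferenceAmplicon) -> str:
        """The PAM as read 5'->3' on the protospacer strand."""
        seq = ref.sequence
        if self.protospacer_strand == "coding":
            if self.pam3_pos < 2 or self.pam3_pos >= len(seq):
                raise ValueError(f"PAM of {self.name} outside reference")
            return seq[self.pam3_pos - 2 : self.pam3_pos + 1]
        if self.pam3_pos < 0 or self.pam3_pos + 3 > len(seq):
            raise ValueError(f"PAM of {self.name} outside reference")
        return revcomp(seq[self.pam3_pos : self.pam3_pos + 3])

    def validate_against(self, ref: ReferenceAmplicon) -> None:
        """Check that spacer and NGG PAM are present at the stated position."""
        pam = self.pam_triplet(ref)
        if pam[1:] != "GG":
            raise ValueError(f"guide {self.name}: PAM {pam} is not NGG")
        seq = ref.sequence
        if self.protospacer_strand == "coding":
            start = self.pam3_pos - 2 - SPACER_LEN
            if start < 0:
                raise ValueError(f"guide {self.name}: protospacer outside reference")
            found = seq[start : start + SPACER_LEN]
        else:
            start = self.pam3_pos + 3
            if start + SPACER_LEN > len(seq):
                raise ValueError(f"guide {self.name}: protospacer outside reference")
            found = revcomp(seq[start : start + SPACER_LEN])
        if found != self.spacer:
            raise ValueError(
                f"guide {self.name}: spacer does not match reference "
                f"(expected {found}, got {self.spacer})"
            )

    def relative_position(self, ref_pos) -> "int | object":
        """PAM-anchored coordinate of a reference position.

        0 is the PAM's 3'-most base; positive values run 5'->3' along the
        coding strand for coding-strand protospacers and are mirrored for
        template-strand protospacers, so profiles from guides on either
        strand overlay in a common frame.  Accepts scalars or arrays.
        """
        if self.protospacer_strand == "coding":
            return ref_pos - self.pam3_pos
        return self.pam3_pos - ref_pos


def find_protospacers(ref: ReferenceAmplicon) -> list[GuideDesign]:
    """Scan both strands for 20-nt protospacers followed by an NGG PAM.

    Returns coding-strand hits first (5'->3'), then template-strand hits
    in their own 5'->3' order (right-to-left on the coding strand).
    Candidate names encode strand and PAM position, e.g. ``c123``/``t123``.
    """
    seq = ref.sequence
    n = len(seq)
    hits: list[GuideDesign] = []
    # coding strand: spacer [p-22, p-2), PAM [p-2, p], NGG => seq[p-1:p+1] == GG
    for p in range(SPACER_LEN + 2, n):
        if seq[p - 1 : p + 1] == "GG":
            hits.append(
                GuideDesign(
                    name=f"c{p}",
                    spacer=seq[p - 2 - SPACER_LEN : p - 2],
                    protospacer_strand="coding",
                    pam3_pos=p,
                )
            )
    # template strand: PAM occupies coding [p, p+3) == CCN, spacer [p+3, p+23)
    for p in range(n - SPACER_LEN - 3, -1, -1):
        if seq[p : p + 2] == "CC":
            hits.append(
                GuideDesign(
                    name=f"t{p}",
                    spacer=revcomp(seq[p + 3 : p + 3 + SPACER_LEN]),
                    protospacer_strand="template",
                    pam3_pos=p,
                )
            )
    return hits


def name_guide(guide: GuideDesign, anchor: int) -> str:
    """Distance-and-side guide name relative to an anchor position.

    Distance is |anchor - pam3_pos| in bp; side is ``L`` when the PAM 3'
    end lies left of the anchor (ties resolve to ``L``); a ``t`` prefix
    marks template-strand protospacers.
    """
    distance = abs(anchor - guide.pam3_pos)
    side = "L" if guide.pam3_pos <= anchor else "R"
    prefix = "t" if guide.protospacer_strand == "template" else ""
    return f"{prefix}{distance}{side}"


_NAME_RE = re.compile(r"^(t?)(\d+)([LR])$")


def parse_guide_name(name: str, anchor: int) -> tuple[str, int]:
    """Invert :func:`name_guide`: recover (strand, pam3_pos) given the anchor."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"unparseable guide name {name!r}")
    strand = "template" if m.group(1) else "coding"
    distance = int(m.group(2))
    pam3 = anchor - distance if m.group(3) == "L" else anchor + distance
    return strand, pam3


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a DNA codon ('*' for stop)."""
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - DNA_ALPHABET:
        raise ValueError(f"invalid codon {codon!r}")
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


def codon_change(ref_codon: str, alt_codon: str) -> tuple[str, str, bool]:
    """Translate a codon substitution; returns (aa_ref, aa_alt, silent)."""
    aa_ref = translate_codon(ref_codon)
    aa_alt = translate_codon(alt_codon)
    return aa_ref, aa_alt, aa_ref == aa_alt


@dataclass
class MutationAnnotation:
    """Coding consequence and feature proximity of one substitution."""

    position: int
    ref: str
    alt: str
    codon_index: int | None  # None outside the ORF
    ref_codon: str | None
    alt_codon: str | None
    aa_ref: str | None
    aa_alt: str | None
    silent: bool | None
    nearest_feature: str | None
    feature_distance: int | None  # 0 inside; negative left of start


def _nearest_feature(pos: int, features: dict[str, tuple[int, int]]):
    best: tuple[str, int] | None = None
    for label, (s, e) in features.items():
        if s <= pos < e:
            d = 0
        elif pos < s:
            d = pos - s
        else:
            d = pos - (e - 1)
        if best is None or abs(d) < abs(best[1]):
            best = (label, d)
    return best


def annotate_mutations(
    mutations: list[tuple[int, str, str]], ref: ReferenceAmplicon
) -> list[MutationAnnotation]:
    """Map substitutions to codon changes and nearest annotated feature.

    Positions outside the ORF (or when no ORF is defined) are annotated as
    non-coding rather than rejected.
    """
    seq = ref.sequence
    out = []
    for pos, ref_base, alt in mutations:
        if not 0 <= pos < len(seq):
            raise ValueError(f"mutation position {pos} outside reference")
        if seq[pos] != ref_base.upper():
            raise ValueError(
                f"mutation ref base {ref_base} does not match reference "
                f"{seq[pos]} at {pos}"
            )
        codon_index = ref_codon = alt_codon = aa_ref = aa_alt = silent = None
        if ref.orf_offset is not None and pos >= ref.orf_offset:
            ci = (pos - ref.orf_offset) // 3
            start = ref.orf_offset + 3 * ci
            if start + 3 <= len(seq):
                codon_index = ci
                ref_codon = seq[start : start + 3]
                offset = pos - start
                alt_codon = ref_codon[:offset] + alt.upper() + ref_codon[offset + 1 :]
                aa_ref, aa_alt, silent = codon_change(ref_codon, alt_codon)
        near = _nearest_feature(pos, ref.features)
        out.append(
            MutationAnnotation(
                position=pos,
                ref=ref_base.upper(),
                alt=alt.upper(),
                codon_index=codon_index,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                aa_ref=aa_ref,
                aa_alt=aa_alt,
                silent=silent,
                nearest_feature=near[0] if near else None,
                feature_distance=near[1] if near else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# TSV / BED-like I/O


def write_guides_tsv(guides: list[GuideDesign], path) -> None:
    pd.DataFrame(
        [
            {
                "name": g.name,
                "spacer": g.spacer,
                "strand": g.protospacer_strand,
                "pam3_pos": g.pam3_pos,
            }
            for g in guides
        ]
    ).to_csv(path, sep="\t", index=False)


def read_guides_tsv(path) -> list[GuideDesign]:
    df = pd.read_csv(path, sep="\t")
    return [
        GuideDesign(
            name=str(r["name"]),
            spacer=str(r["spacer"]),
            protospacer_strand=str(r["strand"]),
            pam3_pos=int(r["pam3_pos"]),
        )
        for _, r in df.iterrows()
    ]


def read_features_bed(path) -> dict[str, tuple[int, int]]:
    """Read 0-based half-open intervals from a BED-like file (chrom start end name)."""
    features: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            start, end = int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start}-{end}"
            features[name] = (start, end)
    return features
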