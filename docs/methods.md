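# Methods

## Generative model of targeted deaminase mutagenesis

The simulator treats the amplicon as a set of independent sites. For a
site at position `i` with PAM-relative distance `d_i` (0 = the 3′-most
base of the NGG on the protospacer strand; template-strand guides are
mirrored so both strands share one frame), the per-genome,
per-generation substitution probability is the product

```
q_i = r · w(d_i) · m(context_i) · s(base_i)
```

- `r` — base rate, per site per generation (default 2.13×10⁻⁴, the
  regime of an active diversifying editor).
- `w(d)` — positional window weight in [0, 1], anchored at the PAM 3′
  end and taken as the max over guides when several target the amplicon.
  Shapes: `uniform` (1 inside ±W, 0 outside; default, W = 50 bp),
  `triangular` (linear decay to 0 at ±W), `gaussian` (σ = W/2,
  unbounded support — the only shape with signal beyond ±W).
- `m(context)` — motif multiplier for the deaminase's sequence
  preference, evaluated on the strand where the C resides (G sites use
  the complementary template context): `agct` for the palindromic AGCT
  core (default 5), `wrcy` for other WRCY with W=A/T, R=A/G, Y=C/T
  (default 2), `other` otherwise (1). A/T sites are always `other`.
  The defaults encode the known AGCT ≫ WRCY ≫ other ordering of AID;
  absolute values for the multipliers are not established, so analyses
  that need neutrality set all three to 1.
- `s(base)` — reference-base multiplier with two classes, C/G (default
  1) and A/T. The A/T entry is the "background" dial: cytidine
  deaminases act on C:G pairs, and the small residual A/T signal in real
  data is modelled as a down-scaled rate at A/T sites. The default
  0.013 puts roughly 1.3% of substitution events at A/T bases on a
  ~50% GC amplicon; `calibrate_at_multiplier` solves the closed-form
  expected share for an exact, composition-aware value (monotone in the
  multiplier, solved by Brent's method).

One modelling note: the window weight multiplies the rate at *every*
site, A/T included, so "background" A/T mutagenesis is also confined to
the guide window rather than spread over the whole amplicon. This keeps
the model a single product and makes the A/T share calibration exact; it
slightly understates truly untargeted background away from the guide,
which is irrelevant for window-restricted statistics.

Over `g` generations the cumulative mutated fraction per site is
`p_i = 1 − (1 − q_i)^g`, applied analytically rather than as discrete
Bernoulli rounds: generation counts derived from OD doublings are
non-integer (20.5 in the default schedule) and only cumulative rates are
observable, so per-round simulation would add cost without adding
fidelity. At most one substitution per site per genome, no
back-mutation. The substituted base comes from a per-reference-base
spectrum; the default C row is C→G 0.50, C→T 0.35, C→A 0.15 (G row
mirrored by complement, A/T rows uniform). The C→G bias direction is a
documented property of this editor class but its exact proportions are
not established; the numbers are package defaults, configurable, and no
test depends on them beyond row-sum validity.

Indels are simulated only as single-base deletions at `indel_rate`
(default 0) — a rarity check, not an indel model.

### Read sampling

Reads emulate paired-end amplicon sequencing (PE250): each pair draws a
genome uniformly with replacement and covers the amplicon from its two
ends on opposite strands, so 2×250 bp over a 400 bp amplicon merge
through a 100 bp overlap. Qualities are constant Q30 with injected
substitution errors marked Q15. Unpaired mode emits reads from the 5′
end and serves as "already-merged" input. Seeding: a master seed feeds
`numpy` `SeedSequence` children — one stream for genome draws, an
independent one for read sampling — so resampling reads (or changing
`n_reads`) never perturbs the genome pool, and identical seeds give
bit-identical pools and read sets.

### What the simulator does not emulate

No PCR bias, chimeras, duplicates, quality miscalibration, population
selection, or multi-contig references. Passing tests therefore
demonstrate correctness of the statistics under an idealised,
binomially-behaved sequencing process — not robustness to real library
artifacts.

## Read processing

**Merging.** For a mate pair, every overlap length from `min_overlap`
(default 10) to the shorter read is scored after reverse-complementing
the mate; the overlap maximising agreeing bases subject to a mismatch
fraction cap (default 0.1) wins, ties to the longer overlap. Consensus
takes the higher-quality base at disagreements; quality is the
per-position max in agreement and min at disagreement. Unmergeable pairs
are counted and dropped (merged-read analysis only), not analysed
single-ended.

**Alignment.** Exact glocal (fitting) alignment — read global,
reference local — under affine gap scoring (match +1, mismatch −1, gap
open −4, extend −1; a gap of length L costs open + (L−1)·extend),
computed by an integer-scored, row-vectorised Gotoh recurrence with
deterministic tie-breaking (diagonal > deletion > insertion, leftmost
end). Alignments below 80% identity are flagged unaligned (a value, not
an error) and excluded downstream. Reference-length reads ≥98% identical
by direct comparison take an ungapped fast path; correctness of the DP
is checked against a naive full-matrix implementation in the tests.
Amplicons are short enough that exact DP replaces a heuristic mapper
outright.

**Pileup.** Per column: `depth_clean` counts reads covering it via
match/substitution only; reads with an insertion (assigned to the column
left of the inserted bases, standard pileup convention) or deletion at
the column move to `indel_count` and out of the clean denominator —
exclusion is per column, not per read. N bases are excluded from
numerator and denominator alike. Coordinates are 0-based half-open
internally; SAM and text-pileup I/O convert to 1-based. No base-quality
filter is applied by default.

## Profiling statistics

- `substitution_rate = Σ alt_counts / depth_clean`, 0 with an explicit
  coverage flag at zero depth; uncovered positions are excluded from
  window means rather than diluted in as zeros.
- Background subtraction operates on rates (sample and background
  depths may differ), position-wise, clamped at zero; counts carried
  from the sample. The spectrum operation rescales count-derived rates
  to the stored (possibly subtracted) per-position rate so its mass
  stays consistent with the window mean.
- Per-generation normalisation divides the window mean by
  `g = Σ log2(OD_end/OD_start)`; plain division rather than the
  compounding-exact `1 − (1−p)^{1/g}`, which differs by <0.2% at these
  magnitudes.
- Multi-guide combination averages rates unweighted across guides at
  each PAM-relative coordinate (depth weighting available but not
  default); the template-strand flip is an involution by construction.
  The window centre convention is the PAM 3′ end throughout.
- Window extent: the shortest contiguous interval containing
  `coverage_frac` (default 0.99) of the summed mean rate; ties resolve
  to the midpoint nearest 0, then leftmost. Note the discretisation: 101
  uniform positions (±50 bp) need 100 of them at 99% coverage, while
  exactly 100 uniform positions need only 99.
- Guide naming: distance from the anchor (first base of the codon of
  interest) to the PAM 3′ end, side L/R (ties to L — the convention is
  silent on a PAM coinciding with its anchor), `t` prefix for
  template-strand protospacers, e.g. `t22L`.

## Affinity fitting

Single-site isotherm `signal = bmax·c/(Kd + c)`, least squares with a
deterministic multi-start grid: 25 log-spaced Kd values spanning the
concentration range widened tenfold either side, bmax seeded from the
maximum signal. Kd is fitted on a log10 scale so screens spanning
nanomolar to picomolar stay well-scaled; the best converged fit must
beat every grid start's own RSS. Confidence half-widths are 1.96·SE from
the fit curvature (delta method back from log Kd). Normalisation to
fitted bmax is available *after* fitting only, to avoid biasing Kd.
Competitive-staining formats are out of scope; the fit applies to
equilibrium titrations.

## Problem sizes and tolerances

End-to-end recovery checks run at 10,000–30,000 genomes with 1,500–
30,000 reads, chosen so closed-form binomial error propagation puts
3 Monte-Carlo SE at a few percent of the recovered quantity; every
stochastic assertion uses a 3 SE band computed from those closed forms,
never a hand-tuned constant. `scripts/acceptance.py` uses 20,000 genomes
with 8,000 read pairs for the window statistics and 200,000 genomes with
200,000 merged-equivalent reads for the A/T share — a rare-category
fraction (~1.3%) needs on the order of 10⁵ substitution events for a
few-percent relative SE, which sets the larger size. Numerical
tolerances elsewhere: spectrum row sums to 1 within 10⁻¹²; alignment
scores are exact integers; rate comparisons use relative 10⁻⁹ unless a
Monte-Carlo band applies.

## Known limitations

- The alignment fast path assumes merged amplicon reads; pathological
  reads that are reference-length yet better aligned with gaps than with
  ≤2% mismatches would bypass the DP (not observed under this data
  model).
- Text-pileup parsing covers the common samtools column grammar
  (`. , ACGT * ^ $ +n/-n`), not every dialect extension.
- `egfp_shift_fraction` compares codons in the reference frame; genomes
  carrying upstream deletions are frame-shifted and simply count as
  non-converted.
- Single-amplicon (single-contig) references only; no mapping-quality
  model; no statistical testing between conditions.
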