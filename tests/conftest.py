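import numpy as np
import pytest

from dbeprof import (
    GuideDesign,
    MutationProfile,
    ReferenceAmplicon,
    SimulationConfig,
    align_read,
    build_pileup,
    merge_readset,
    sample_reads,
    simulate_mutagenesis,
)
from dbeprof.simulate import expected_site_fractions

NEUTRAL_MOTIF = {"agct": 1.0, "wrcy": 1.0, "other": 1.0}


def make_amplicon(seed=7, length=400, pam3=202):
    """Random amplicon with a coding-strand NGG PAM whose 3' base is pam3."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), length))
    seq = seq[: pam3 - 2] + "TGG" + seq[pam3 + 1 :]
    ref = ReferenceAmplicon("amp", seq)
    guide = GuideDesign("g1", seq[pam3 - 22 : pam3 - 2], "coding", pam3)
    guide.validate_against(ref)
    return ref, guide


def uniform_config(ref, guide, **overrides):
    """Uniform-window configuration: motif and base multipliers all 1."""
    kwargs = dict(
        reference=ref,
        guides=[guide],
        base_rate_r=2.13e-4,
        window_halfwidth=50,
        motif_multiplier=dict(NEUTRAL_MOTIF),
        base_multiplier={"CG": 1.0, "AT": 1.0},
        generations=20.5,
        n_genomes=2000,
        read_length=250,
        paired=True,
        seq_error_rate=0.0,
        seed=1,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def amplicon():
    return make_amplicon()


@pytest.fixture(scope="session")
def uniform_chain(amplicon):
    """Full simulate->merge->align->pileup chain under uniform conditions.

    Shared by the end-to-end recovery checks; sized so Monte-Carlo error
    on the window mean is a few percent.
    """
    ref, guide = amplicon
    config = uniform_config(ref, guide, n_genomes=10_000, seed=11)
    pool = simulate_mutagenesis(config)
    reads = sample_reads(pool, 1500, 250, True, 0.0, seed=11)
    merged, unmerged = merge_readset(reads)
    alignments = [align_read(r, ref) for r in merged.singles]
    cols = build_pileup(alignments, ref)
    profile = MutationProfile.from_pileup(cols, ref.id)
    return {
        "ref": ref,
        "guide": guide,
        "config": config,
        "pool": pool,
        "n_reads": 1500,
        "unmerged": unmerged,
        "alignments": alignments,
        "profile": profile,
        "p_expected": expected_site_fractions(config),
    }
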