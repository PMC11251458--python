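import pytest

import ribofrag as rf


@pytest.fixture(scope="session")
def small_transcriptome():
    """A 60-gene random transcriptome, fixed seed, with uORFs on ~30%."""
    return rf.build_transcriptome(60, seed=42)


@pytest.fixture()
def toy_transcript():
    """One hand-built transcript: 20 nt 5'UTR, 30 nt CDS, 20 nt 3'UTR."""
    utr5 = "GGGGGGGGGGGGGGGGGGGG"
    cds = "AUG" + "GGC" * 8 + "UAA"
    utr3 = "GGGGGGGGGGGGGGGGGGGG"
    return rf.TranscriptModel("toy", utr5 + cds + utr3, 20, 50)


def simulate_library(seed, intensity, reinit_prob, stall_weight=0.0,
                     n_genes=60, copies=60, density=0.2, baseline_loss=0.7,
                     nuclease=rf.RNASE_L):
    """Standard study-condition simulation used across tests: transcriptome,
    cleavage, translation, footprint processing into raw P-site profiles."""
    ts = rf.build_transcriptome(n_genes, seed=seed)
    expr = rf.ExpressionState.uniform(ts, copies)
    pool = rf.fragment_pool(
        ts, expr, nuclease,
        rf.FragmentationParams(intensity, baseline_loss, seed + 1000))
    tparams = rf.TranslationParams(density=density, reinit_prob=reinit_prob,
                                   stall_weight=stall_weight, seed=seed + 2000)
    reads = rf.simulate_footprints(pool, ts, tparams)
    reads = rf.dedup_umi(rf.filter_by_length(reads))
    profiles = rf.build_profiles(reads, {t.id: t.length for t in ts})
    return ts, pool, reads, profiles
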