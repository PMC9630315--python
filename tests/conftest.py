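import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import triplexkit as tk
from triplexkit.triplex import decode_bases

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BASES = "ACGT"


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, n))


def random_rna(n: int, rng: np.random.Generator) -> str:
    return random_dna(n, rng).replace("T", "U")


def skewed_dna(n: int, rng: np.random.Generator, p_acgt) -> str:
    """i.i.d. sequence with an explicit (A, C, G, T) composition."""
    return decode_bases(rng.choice(4, size=n, p=list(p_acgt)).astype("int8"))


@pytest.fixture
def ga_tfo() -> tk.NucleicSeq:
    """A motif-pure purine TFO: perfect planted sites have zero mismatches."""
    return tk.NucleicSeq("ga_tfo", "RNA", "GGAGGAAAGAGAAAGG")


@pytest.fixture
def planted_world(ga_tfo):
    """Small genome with planted TTS plus an lncRNA with a planted TFR."""
    genome, _ = tk.make_genome(n_chroms=1, chrom_len=3000, gc_fraction=0.5, seed=1)
    genome, tts_truth = tk.plant_tts(genome, ga_tfo, n_sites=6,
                                     mismatch_rate=0.0, seed=2)
    rna, tfr_span = tk.make_lncrna(120, ga_tfo, seed=3)
    return {"genome": genome, "tts_truth": tts_truth, "rna": rna,
            "tfr_span": tfr_span, "tfo": ga_tfo}
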