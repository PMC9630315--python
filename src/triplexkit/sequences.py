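"""In-study oligonucleotide constructs and fitted melting transitions.

These are the nucleotide sequences used in the EMSA, CD/melting and NMR
characterization of the HIF1α-AS1 TFR2 triplexes with its EPHA2 and ADM
target sites, together with the published fitted melting midpoints. They
serve as fixed reference inputs for the sequence-level checks and for the
melting-model recovery runs.

Strand naming follows computable base content: the "GA" strand of each
duplex is the purine-rich strand the RNA third strand reads in the major
groove, the "CT" strand is its Watson-Crick complement.
"""

from __future__ import annotations

from .triplex import NucleicSeq

# HIF1α-AS1 TFR2 third strand (TFO2-23), 23 nt. This oligo's published
# GC annotation (50.9%) disagrees with its sequence, which computes to
# 14/23 = 60.9%; the computed value is used throughout.
TFO2_23 = NucleicSeq(
    "TFO2-23", "RNA", "GCGGCGGAGGAAAGAGAAAGGAG",
    description="HIF1a-AS1 TFR2 triplex-forming oligonucleotide (RNA)",
)

# EPHA2 intron-1 triplex target site, 25 bp duplex (hg19 chr1:16,478,543-16,478,567).
EPHA2_GA = NucleicSeq(
    "EPHA2_GA", "DNA", "AGAGGGTAAGGAGATAGGAGAAACC",
    description="EPHA2 TTS purine-rich strand",
)
EPHA2_CT = NucleicSeq(
    "EPHA2_CT", "DNA", "GGTTTCTCCTATCTCCTTACCCTCT",
    description="EPHA2 TTS pyrimidine-rich strand",
)
EPHA2_LOCUS = "chr1:16,478,543-16,478,567"

# ADM triplex target site, 15 bp duplex (hg19 chr11:10,326,521-10,326,535).
ADM_GA = NucleicSeq(
    "ADM_GA", "DNA", "GTGGCTGAGGAAAGA",
    description="ADM TTS purine-rich strand",
)
ADM_CT = NucleicSeq(
    "ADM_CT", "DNA", "TCTTTCCTCAGCCAC",
    description="ADM TTS pyrimidine-rich strand",
)
ADM_LOCUS = "chr11:10,326,521-10,326,535"

#: Thymidine linker joining the two duplex strands into an intramolecular hairpin.
HAIRPIN_LINKER = "TTTTT"

# Hairpin constructs as printed: CT-rich strand + T5 linker + GA-rich strand.
EPHA2_HAIRPIN = NucleicSeq(
    "EPHA2_hairpin", "DNA",
    EPHA2_CT.bases + HAIRPIN_LINKER + EPHA2_GA.bases,
    description="EPHA2 TTS hairpin (CT strand + T5 + GA strand), 55 nt",
)
ADM_HAIRPIN = NucleicSeq(
    "ADM_hairpin", "DNA",
    ADM_CT.bases + HAIRPIN_LINKER + ADM_GA.bases,
    description="ADM TTS hairpin (CT strand + T5 + GA strand), 35 nt",
)


def make_hairpin(ct_strand: NucleicSeq, ga_strand: NucleicSeq,
                 linker: str = HAIRPIN_LINKER) -> NucleicSeq:
    """Assemble an intramolecular duplex hairpin: CT strand + linker + GA strand."""
    return NucleicSeq(
        f"{ct_strand.id}+{ga_strand.id}_hairpin", "DNA",
        ct_strand.bases + linker + ga_strand.bases,
        description=f"hairpin of {ct_strand.id}/{ga_strand.id} with {len(linker)} nt linker",
    )


#: Fitted melting midpoints (°C) reported for each construct, as
#: (first transition, second transition) — None where monophasic.
PUBLISHED_TM = {
    "EPHA2_heteroduplex": (53.48, None),
    "EPHA2_duplex": (70.74, None),
    "EPHA2_triplex": (49.52, 70.0),   # second transition very broad, ~70 °C
    "EPHA2_hairpin": (80.41, None),
    "EPHA2_hairpin_triplex": (50.08, 79.90),
    "ADM_duplex": (63.80, None),
    "ADM_hairpin": (95.76, None),
    "ADM_hairpin_triplex": (40.24, 81.78),
}
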