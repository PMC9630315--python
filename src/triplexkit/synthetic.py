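"""Synthetic inputs with known ground truth for every pipeline stage.

Everything the analysis consumes can be generated here: random genomes
with planted triplex target sites, lncRNAs with planted triplex-forming
regions, per-lncRNA peak tables with Poisson-distributed counts, qPCR Ct
tables with known fold changes, and melting curves drawn from the
double-sigmoid model. Each generator is deterministic under its seed and
records what it planted, so downstream stages can be tested for exact
recovery without any external download.

Background sequence is i.i.d. at a requested GC fraction — a deliberate
simplification (no dinucleotide structure) sufficient for exercising a
pattern search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .melting import MeltingCurve, eval_model
from .triplex import (
    NucleicSeq, TRIPLEX_CODES, _BASE_INDEX, _INDEX_BASE,
    encode_bases, decode_bases, reverse_complement,
)


class CapacityError(ValueError):
    """Requested placements do not fit in the available sequence space."""


def place_nonoverlapping(lengths, space: int, rng: np.random.Generator) -> list[int]:
    """Uniformly random non-overlapping start positions for given lengths.

    Draws an exact uniform sample over all non-overlapping configurations
    (in the given length order) by placing the intervals into the free
    space left after removing their total length. Returns start positions
    aligned with ``lengths``.
    """
    lengths = list(int(x) for x in lengths)
    total = sum(lengths)
    free = space - total
    if free < 0:
        raise CapacityError(
            f"cannot place intervals of total length {total} in space {space}"
        )
    if not lengths:
        return []
    gaps = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    offsets = np.concatenate([[0], np.cumsum(lengths[:-1])])
    return [int(g + o) for g, o in zip(gaps, offsets)]


# --------------------------------------------------------------------------
# Ground-truth manifest
# --------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Machine-readable manifest of everything a generation run planted."""

    genome_id: str = ""
    seed: int = 0
    planted_tts: list = field(default_factory=list)   # (chrom, start, end, purine_strand)
    planted_tfr: tuple | None = None                  # (rna_id, start, end)
    peak_truth: list = field(default_factory=list)    # (lncrna_id, lambda, mean, enriched)
    melt_truth: list = field(default_factory=list)    # (curve_id, a, x0, b, c, x2, d, sd)
    ct_truth: list = field(default_factory=list)      # (sample_id, true_fold)

    def validate(self, genome: dict[str, str] | None = None):
        for chrom, start, end, strand in self.planted_tts:
            if start >= end:
                raise ValueError(f"planted TTS {chrom}:{start}-{end} has start >= end")
            if strand not in ("+", "-"):
                raise ValueError(f"planted TTS strand must be +/-, got {strand!r}")
            if genome is not None and (chrom not in genome or end > len(genome[chrom])):
                raise ValueError(f"planted TTS {chrom}:{start}-{end} outside genome bounds")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def write(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["planted_tts"] = [tuple(x) for x in d.get("planted_tts", [])]
        if d.get("planted_tfr") is not None:
            d["planted_tfr"] = tuple(d["planted_tfr"])
        for key in ("peak_truth", "melt_truth", "ct_truth"):
            d[key] = [tuple(x) for x in d.get(key, [])]
        return cls(**d)

    @classmethod
    def read(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls.from_json(fh.read())


# --------------------------------------------------------------------------
# Genomes and planted triplex target sites
# --------------------------------------------------------------------------

def make_genome(n_chroms: int = 1, chrom_len: int = 10_000,
                gc_fraction: float = 0.5, seed: int = 0):
    """i.i.d. random genome at a requested GC fraction.

    Returns (genome dict chrom->sequence, manifest dict). Base composition
    is A/T split of (1-GC) and G/C split of GC, independent per position.
    """
    if n_chroms < 1 or chrom_len < 100:
        raise ValueError("need n_chroms >= 1 and chrom_len >= 100")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    genome = {}
    for i in range(n_chroms):
        codes = rng.choice(4, size=chrom_len, p=p)
        genome[f"chr{i + 1}"] = decode_bases(codes)
    manifest = {
        "seed": seed, "n_chroms": n_chroms, "chrom_len": chrom_len,
        "gc_fraction": gc_fraction,
    }
    return genome, manifest


def _pairing_table(motif: str | None) -> tuple[np.ndarray, str]:
    """(allowed-pair table, orientation) for a motif, or the combined code.

    ``motif=None`` unions the canonical codes so every third-strand base
    has a partner (G·G:C, A·A:T, T·A:T, C·G:C); combined-code sites are
    placed in the antiparallel frame of the purine motif.
    """
    if motif is None:
        table = np.zeros((4, 4), dtype=bool)
        for code in TRIPLEX_CODES.values():
            table |= code.table
        return table, "antiparallel"
    code = TRIPLEX_CODES[motif]
    return code.table, code.orientation


def hoogsteen_target_strand(tfo: NucleicSeq, motif: str | None = None) -> str:
    """The purine strand (5'->3') that pairs perfectly with ``tfo``.

    The pairing table maps every third-strand base to one canonical duplex
    purine partner (identity preferred: G·G, A·A); the strand is reversed
    for antiparallel frames so that position i of the TFO faces its
    partner in the duplex. With ``motif=None`` the combined Hoogsteen code
    is used, so mixed-sequence TFOs such as TFO2-23 also get a perfect
    site; under a single strict motif a TFO base without a partner raises.
    """
    table, orientation = _pairing_table(motif)
    partner = {}
    for t in range(4):
        purines = np.flatnonzero(table[t])
        if len(purines):
            # prefer the identity partner (G·G, A·A), else the unique purine
            partner[t] = int(t) if t in purines else int(purines[0])
    mapped = []
    for b in tfo.encoded():
        if int(b) not in partner:
            raise ValueError(
                f"TFO base {_INDEX_BASE[b]!r} has no partner under motif {motif!r}"
            )
        mapped.append(partner[int(b)])
    strand = decode_bases(np.array(mapped, dtype=np.int8))
    return strand[::-1] if orientation == "antiparallel" else strand


def plant_tts(genome: dict[str, str], tfo: NucleicSeq, n_sites: int,
              mismatch_rate: float = 0.0, seed: int = 0,
              motif: str | None = None, min_tfo_len: int = 12):
    """Write Hoogsteen-matching duplex target sites into a genome.

    Each site is the perfect purine-strand partner of ``tfo`` (under the
    combined Hoogsteen code by default, or a single strict ``motif``) with
    floor(mismatch_rate * len) positions mutated to a disallowed base,
    written at a uniformly random non-overlapping position on a randomly
    chosen strand. Returns (new genome, truth intervals) with intervals as
    (chrom, start, end, purine_strand), 0-based half-open in plus
    coordinates.
    """
    if len(tfo) < min_tfo_len:
        raise ValueError(f"TFO length {len(tfo)} below minimum {min_tfo_len}")
    if not 0.0 <= mismatch_rate < 1.0:
        raise ValueError("mismatch_rate must lie in [0, 1)")
    if n_sites < 0:
        raise ValueError("n_sites must be non-negative")
    rng = np.random.default_rng(seed)
    perfect = hoogsteen_target_strand(tfo, motif)
    L = len(perfect)
    table, orientation = _pairing_table(motif)
    # duplex bases never allowed for the facing TFO base
    tfo_rev = tfo.encoded()[::-1] if orientation == "antiparallel" else tfo.encoded()

    new_genome = dict(genome)
    truth: list[tuple[str, int, int, str]] = []
    n_mismatch = int(np.floor(mismatch_rate * L))
    chroms = sorted(genome)
    chrom_pick = rng.choice(len(chroms), size=n_sites) if n_sites else []
    per_chrom: dict[str, int] = {c: 0 for c in chroms}
    for ci in chrom_pick:
        per_chrom[chroms[int(ci)]] += 1

    for chrom in chroms:
        k = per_chrom[chrom]
        if k == 0:
            continue
        starts = place_nonoverlapping([L] * k, len(genome[chrom]), rng)
        seq = list(new_genome[chrom])
        for start in starts:
            site = encode_bases(perfect)
            if n_mismatch:
                pos = rng.choice(L, size=n_mismatch, replace=False)
                for j in pos:
                    disallowed = np.flatnonzero(~table[tfo_rev[j]])
                    site[j] = int(disallowed[rng.integers(len(disallowed))])
            strand = "+" if rng.random() < 0.5 else "-"
            written = decode_bases(site)
            if strand == "-":
                written = reverse_complement(written)
            seq[start:start + L] = written
            truth.append((chrom, int(start), int(start + L), strand))
        new_genome[chrom] = "".join(seq)
    truth.sort()
    return new_genome, truth


def make_lncrna(length: int, tfo: NucleicSeq, tfr_start: int | None = None,
                gc_fraction: float = 0.5, seed: int = 0,
                rna_id: str = "synthetic_lncrna"):
    """Random lncRNA with the TFO embedded as a planted triplex-forming region.

    Returns (NucleicSeq RNA, (start, end) of the planted region). With
    ``tfr_start=None`` the region is placed centrally.
    """
    L = len(tfo)
    if length < L:
        raise ValueError("lncRNA shorter than the TFO to embed")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    codes = rng.choice(4, size=length, p=p)
    start = (length - L) // 2 if tfr_start is None else int(tfr_start)
    if not 0 <= start <= length - L:
        raise ValueError("tfr_start places the TFO outside the RNA")
    codes[start:start + L] = encode_bases(tfo.dna_bases)
    bases = decode_bases(codes).replace("T", "U")
    return NucleicSeq(rna_id, "RNA", bases), (start, start + L)


# --------------------------------------------------------------------------
# Peak tables (Triplex-Seq summary emulation)
# --------------------------------------------------------------------------

def make_peak_table(n_lncrnas: int = 1000, n_enriched: int = 10,
                    background_lambda: float = 5.0, enriched_fold: float = 20.0,
                    seed: int = 0):
    """Per-lncRNA peak counts: Poisson background with planted enrichment.

    Observed counts are Poisson(lambda) for background rows and
    Poisson(lambda * enriched_fold) for the ``n_enriched`` randomly chosen
    enriched rows; the expected column carries lambda. Returns
    (peak table, truth table).
    """
    if n_enriched > n_lncrnas:
        raise ValueError("n_enriched cannot exceed n_lncrnas")
    if background_lambda <= 0 or enriched_fold <= 0:
        raise ValueError("background_lambda and enriched_fold must be positive")
    rng = np.random.default_rng(seed)
    enriched = np.zeros(n_lncrnas, dtype=bool)
    enriched[rng.choice(n_lncrnas, size=n_enriched, replace=False)] = True
    lam = np.where(enriched, background_lambda * enriched_fold, background_lambda)
    observed = rng.poisson(lam)
    ids = [f"LNC{i:05d}" for i in range(n_lncrnas)]
    width = 500
    peaks = pd.DataFrame({
        "lncrna_id": ids,
        "chrom": "chrS",
        "start": np.arange(n_lncrnas) * 2 * width,
        "end": np.arange(n_lncrnas) * 2 * width + width,
        "observed_reads": observed,
        "expected_reads": float(background_lambda),
    })
    truth = pd.DataFrame({
        "lncrna_id": ids,
        "true_lambda": lam,
        "true_observed_mean": lam,
        "is_enriched": enriched,
    })
    return peaks, truth


#: FANTOM5-style endothelial tissue panel used by the expression filter.
TISSUE_COLUMNS = (
    "aorta", "artery", "lymphatic", "microvascular",
    "thoracic", "umbilical_vein", "vein",
)


def make_candidate_table(peaks: pd.DataFrame, truth: pd.DataFrame, seed: int = 0,
                         frac_no_nuclear: float = 0.0,
                         frac_coding: float = 0.0,
                         frac_gene_conflict: float = 0.0) -> pd.DataFrame:
    """Screening rows for a peak table: expression, coding and conflict columns.

    By default every row gets passing annotation values (positive nuclear
    and tissue signals, non-coding probability, no overlapping-gene
    conflict) so that screen outcomes are driven by the peak statistics;
    the ``frac_*`` arguments independently mark random row subsets as
    failing one annotation filter each.
    """
    rng = np.random.default_rng(seed)
    n = len(peaks)
    df = peaks[["lncrna_id", "observed_reads", "expected_reads"]].copy()
    df["present_in_both_cell_lines"] = True
    df["nuclear_signal"] = rng.uniform(0.5, 10.0, size=n)
    for col in TISSUE_COLUMNS:
        df[col] = rng.uniform(0.1, 5.0, size=n)
    df["coding_probability"] = rng.uniform(0.0, 0.3, size=n)
    df["overlapping_gene_conflict"] = False
    if frac_no_nuclear > 0:
        idx = df.index[rng.random(n) < frac_no_nuclear]
        df.loc[idx, "nuclear_signal"] = 0.0
    if frac_coding > 0:
        idx = df.index[rng.random(n) < frac_coding]
        df.loc[idx, "coding_probability"] = rng.uniform(0.5, 1.0, size=len(idx))
    if frac_gene_conflict > 0:
        idx = df.index[rng.random(n) < frac_gene_conflict]
        df.loc[idx, "overlapping_gene_conflict"] = True
    df["is_enriched_truth"] = truth["is_enriched"].to_numpy()
    return df


# --------------------------------------------------------------------------
# Melting curves and Ct tables
# --------------------------------------------------------------------------

def make_melting_curve(a: float = 0.5, x0: float = 49.52, b: float = 3.0,
                       c: float = 0.5, x2: float = 70.0, d: float = 3.0,
                       t_min: float = 5.0, t_max: float = 95.0,
                       step: float = 0.5, noise_sd: float = 0.0,
                       seed: int = 0, curve_id: str = "synthetic_melt") -> MeltingCurve:
    """Melting curve drawn from the double-sigmoid model plus Gaussian noise."""
    if t_min >= t_max:
        raise ValueError("t_min must be below t_max")
    if b <= 0 or d <= 0:
        raise ValueError("slope parameters b and d must be positive")
    t = np.arange(t_min, t_max + step / 2, step)
    v = eval_model((a, x0, b, c, x2, d), t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=len(t))
    return MeltingCurve(t, v, curve_id)


def make_ct_table(true_fold_changes, base_ct: float = 25.0,
                  noise_sd: float = 0.0, seed: int = 0,
                  reference_ct: float = 18.0, n_replicates: int = 3):
    """qPCR Ct tables with known treated-vs-control fold changes.

    A fold change F lowers the treated target Ct by log2(F) cycles against
    a constant reference gene, so the delta-delta-Ct statistic recovers F
    exactly at zero noise. Returns (long-format Ct table, truth table).
    """
    folds = [float(f) for f in true_fold_changes]
    if any(f <= 0 for f in folds):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for i, fold in enumerate(folds):
        sample = f"S{i + 1}"
        for rep in range(1, n_replicates + 1):
            for condition, tgt in (
                ("control", base_ct),
                ("treated", base_ct - np.log2(fold)),
            ):
                rows.append({
                    "sample_id": sample, "condition": condition, "replicate": rep,
                    "target_ct": tgt + rng.normal(0, noise_sd) if noise_sd else tgt,
                    "reference_ct": (reference_ct + rng.normal(0, noise_sd)
                                     if noise_sd else reference_ct),
                })
    table = pd.DataFrame(rows)
    truth = pd.DataFrame({
        "sample_id": [f"S{i + 1}" for i in range(len(folds))],
        "true_fold": folds,
    })
    return table, truth
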