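"""Triplex-forming-region discovery with a shuffle-based empirical null.

Which part of an RNA is a triplex-forming region (TFR) is decided against
a set of candidate DNA target regions: RNA windows supported by triplex
hits are scored by the number of target regions they hit, and that count
is compared with a null distribution obtained by re-scoring the RNA
against position-shuffled copies of the same regions (identical lengths,
same chromosome, uniformly random non-overlapping placement). The
empirical p-value uses the plus-one estimator (r+1)/(n+1), so it can never
reach zero and its minimum is 1/(n_randomizations+1).

No multiple-testing correction is applied across windows; enrichment is
reported at the raw alpha, which is a documented caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import place_nonoverlapping, CapacityError  # noqa: F401  (re-export)
from .triplex import (
    NucleicSeq, TriplexHit, find_tts, find_tts_many,
    DEFAULT_MIN_LEN, DEFAULT_MAX_ERROR_RATE, DEFAULT_MOTIFS,
)

DEFAULT_N_RANDOMIZATIONS = 200
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class RegionSet:
    """Genomic intervals (0-based half-open) with their chromosome bounds."""

    regions: tuple
    genome_bounds: dict

    def __post_init__(self):
        regs = tuple((str(c), int(s), int(e)) for c, s, e in self.regions)
        for chrom, start, end in regs:
            if start >= end:
                raise ValueError(f"region {chrom}:{start}-{end} has start >= end")
            if chrom not in self.genome_bounds:
                raise ValueError(f"region chromosome {chrom!r} not in genome bounds")
            if start < 0 or end > self.genome_bounds[chrom]:
                raise ValueError(f"region {chrom}:{start}-{end} outside chromosome")
        object.__setattr__(self, "regions", regs)

    def __len__(self) -> int:
        return len(self.regions)


def shuffle_regions(region_set: RegionSet, seed=None,
                    rng: np.random.Generator | None = None) -> RegionSet:
    """Place the same regions uniformly at random on their own chromosomes.

    Lengths and chromosome assignment are preserved; placements are
    mutually non-overlapping. Raises ``CapacityError`` when a chromosome
    cannot hold its regions.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[int]] = {}
    for idx, (chrom, start, end) in enumerate(region_set.regions):
        by_chrom.setdefault(chrom, []).append(idx)
    new_regions = [None] * len(region_set.regions)
    for chrom in sorted(by_chrom):
        idxs = by_chrom[chrom]
        lengths = [region_set.regions[i][2] - region_set.regions[i][1] for i in idxs]
        order = rng.permutation(len(idxs))
        starts = place_nonoverlapping([lengths[i] for i in order],
                                      region_set.genome_bounds[chrom], rng)
        for slot, start in zip(order, starts):
            i = idxs[slot]
            new_regions[i] = (chrom, start, start + lengths[slot])
    return RegionSet(tuple(new_regions), region_set.genome_bounds)


@dataclass(frozen=True)
class TFR:
    """A triplex-forming region of the RNA with its empirical enrichment."""

    rna_id: str
    start: int
    end: int
    n_target_regions_hit: int
    null_counts: tuple
    empirical_p: float
    n_randomizations: int

    def __post_init__(self):
        n = self.n_randomizations
        if not (1 / (n + 1) - 1e-12 <= self.empirical_p <= 1 + 1e-12):
            raise ValueError("empirical p outside [1/(n+1), 1]")


def _region_seq(genome: dict[str, str], chrom: str, start: int, end: int) -> NucleicSeq:
    return NucleicSeq(chrom, "DNA", genome[chrom][start:end])


def _scan_regions(rna: NucleicSeq, regions, genome, scan_params):
    """Per-region lists of RNA-side hit intervals (tfo_start, tfo_end).

    All maximal matches are kept (no same-motif overlap merging): the
    enrichment statistic only asks whether a region carries a hit at an
    RNA position, for which the unmerged union is the natural support.
    """
    seqs = [_region_seq(genome, c, s, e) for c, s, e in regions]
    hit_lists = find_tts_many(rna, seqs, merge=False, **scan_params)
    return [[(h.tfo_start, h.tfo_end) for h in hits] for hits in hit_lists]


def _coverage_windows(rna_len: int, interval_lists):
    """Maximal runs of RNA positions covered by >= 1 hit."""
    cov = np.zeros(rna_len + 1, dtype=np.int32)
    for intervals in interval_lists:
        for s, e in intervals:
            cov[s] += 1
            cov[e] -= 1
    covered = np.cumsum(cov[:-1]) > 0
    windows = []
    in_run = False
    for i, c in enumerate(covered):
        if c and not in_run:
            run_start, in_run = i, True
        elif not c and in_run:
            windows.append((run_start, i))
            in_run = False
    if in_run:
        windows.append((run_start, rna_len))
    return windows


def _count_regions_hitting(windows, interval_lists):
    """For each window, the number of regions with >= 1 overlapping hit."""
    counts = np.zeros(len(windows), dtype=np.int64)
    for intervals in interval_lists:
        seen = np.zeros(len(windows), dtype=bool)
        for s, e in intervals:
            for w, (ws, we) in enumerate(windows):
                if s < we and ws < e:
                    seen[w] = True
        counts += seen
    return counts


def discover_tfrs(rna: NucleicSeq, region_set: RegionSet, genome: dict[str, str],
                  scan_params: dict | None = None,
                  n_randomizations: int = DEFAULT_N_RANDOMIZATIONS,
                  alpha: float = DEFAULT_ALPHA, seed: int = 0,
                  windows=None) -> list[TFR]:
    """Statistically enriched triplex-forming regions of an RNA.

    Candidate windows are the maximal runs of RNA positions covered by at
    least one triplex hit against the target regions; each window's
    statistic is the number of regions hit. The null re-scores the RNA
    against ``n_randomizations`` shuffled region sets, and windows with
    empirical p < alpha are reported as TFRs (overlapping or abutting
    significant windows merged, keeping the smallest p).

    ``windows`` fixes the candidate RNA windows a priori (a list of
    (start, end) intervals) instead of deriving them from the observed
    hits — used e.g. for null calibration, where a data-independent
    window makes the rank statistic exactly exchangeable.
    """
    if n_randomizations < 1:
        raise ValueError("need at least one randomization")
    if len(region_set) == 0:
        warnings.warn("empty region set: no TFRs can be discovered", stacklevel=2)
        return []
    params = {
        "min_len": DEFAULT_MIN_LEN, "max_error_rate": DEFAULT_MAX_ERROR_RATE,
        "motifs": DEFAULT_MOTIFS,
    }
    if scan_params:
        unknown = set(scan_params) - set(params)
        if unknown:
            raise ValueError(f"unknown scan parameters {sorted(unknown)}")
        params.update(scan_params)

    observed_lists = _scan_regions(rna, region_set.regions, genome, params)
    if windows is None:
        windows = _coverage_windows(len(rna), observed_lists)
    else:
        windows = [(int(s), int(e)) for s, e in windows]
        if any(s >= e or s < 0 or e > len(rna) for s, e in windows):
            raise ValueError("fixed windows must be non-empty intervals on the RNA")
    if not windows:
        return []
    observed = _count_regions_hitting(windows, observed_lists)

    rng = np.random.default_rng(seed)
    null = np.zeros((n_randomizations, len(windows)), dtype=np.int64)
    for r in range(n_randomizations):
        shuffled = shuffle_regions(region_set, rng=rng)
        null_lists = _scan_regions(rna, shuffled.regions, genome, params)
        null[r] = _count_regions_hitting(windows, null_lists)

    n = n_randomizations
    pvals = (1 + (null >= observed[None, :]).sum(axis=0)) / (1 + n)

    significant = [
        (ws, we, int(obs), tuple(int(x) for x in null[:, w]), float(p))
        for w, ((ws, we), obs, p) in enumerate(zip(windows, observed, pvals))
        if p < alpha
    ]
    significant.sort()
    merged: list[list] = []
    for ws, we, obs, null_c, p in significant:
        if merged and ws <= merged[-1][1]:
            last = merged[-1]
            last[1] = max(last[1], we)
            if p < last[4]:
                last[2], last[3], last[4] = obs, null_c, p
        else:
            merged.append([ws, we, obs, null_c, p])
    return [
        TFR(rna.id, ws, we, obs, null_c, p, n)
        for ws, we, obs, null_c, p in merged
    ]


def _merge_intervals(intervals):
    """Merge overlapping/abutting (chrom, start, end) intervals."""
    out = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            out[-1][2] = max(out[-1][2], end)
        else:
            out.append([chrom, start, end])
    return [tuple(x) for x in out]


def overlap_tts(tfr_hit_sets) -> tuple[list[tuple[str, int, int]], int]:
    """Genomic intervals shared (>= 1 bp overlap) by every hit set.

    Each hit set may hold ``TriplexHit`` objects or plain (chrom, start,
    end) tuples; per-set intervals are merged first, then intersected
    across all sets. Order of the sets does not matter. Returns (shared
    intervals, their count).
    """
    sets = list(tfr_hit_sets)
    if len(sets) < 2:
        raise ValueError("need at least two hit sets to overlap")
    merged_sets = []
    for hits in sets:
        intervals = [
            (h.chrom, h.start, h.end) if isinstance(h, TriplexHit) else tuple(h)
            for h in hits
        ]
        merged_sets.append(_merge_intervals(intervals))
    shared = merged_sets[0]
    for other in merged_sets[1:]:
        nxt = []
        for chrom, s1, e1 in shared:
            for chrom2, s2, e2 in other:
                if chrom == chrom2:
                    lo, hi = max(s1, s2), min(e1, e2)
                    if lo < hi:
                        nxt.append((chrom, lo, hi))
        shared = _merge_intervals(nxt)
        if not shared:
            break
    return shared, len(shared)
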