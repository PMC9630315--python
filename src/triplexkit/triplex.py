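"""Hoogsteen pairing code and mismatch-tolerant triplex search.

A DNA:DNA:RNA triplex forms when a single-stranded RNA (the triplex-forming
oligonucleotide, TFO) lies in the major groove of duplex DNA and reads the
purine-rich strand via Hoogsteen or reverse-Hoogsteen hydrogen bonds. The
pairing is gapless and positionally collinear: TFO base i contacts exactly
one base pair of the duplex, so a candidate triplex is a window of the TFO
aligned without gaps against a window of the duplex, in one of two
orientations relative to the purine strand.

This module implements:

* the canonical pairing codes per motif (purine, pyrimidine, mixed),
* ``purine_tracts`` — purine-rich target-site discovery on either strand,
* ``find_tts`` — enumeration of all maximal mismatch-bounded TFO↔duplex
  matches over both strands and all enabled motifs.

Coordinates are 0-based half-open throughout. Minus-strand features are
reported in plus-strand coordinates with a strand flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

# --------------------------------------------------------------------------
# Alphabets and encoding
# --------------------------------------------------------------------------

_DNA_BASES = set("ACGT")
_RNA_BASES = set("ACGU")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_INDEX_BASE = "ACGT"

#: numeric complement: A<->T, C<->G under the 0..3 encoding
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)


def _normalize_base(base: str) -> str:
    """Uppercase a single base and map U to T for comparison purposes."""
    b = base.upper()
    if b == "U":
        b = "T"
    if b not in _DNA_BASES:
        raise ValueError(
            f"unknown or ambiguous base {base!r}: only unambiguous A/C/G/T/U "
            "are accepted (IUPAC ambiguity codes are rejected)"
        )
    return b


@dataclass(frozen=True)
class NucleicSeq:
    """An identified single-stranded DNA or RNA sequence.

    Bases must be unambiguous and drawn from the declared alphabet
    (``ACGT`` for DNA, ``ACGU`` for RNA). U/T equivalence is applied at
    comparison time only; the stored sequence keeps its alphabet.
    """

    id: str
    alphabet: str
    bases: str
    description: str = ""

    def __post_init__(self):
        if self.alphabet not in ("DNA", "RNA"):
            raise ValueError(f"alphabet must be 'DNA' or 'RNA', got {self.alphabet!r}")
        object.__setattr__(self, "bases", self.bases.upper())
        if len(self.bases) < 1:
            raise ValueError("sequence must contain at least one base")
        valid = _DNA_BASES if self.alphabet == "DNA" else _RNA_BASES
        bad = set(self.bases) - valid
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters {sorted(bad)} outside "
                f"the {self.alphabet} alphabet (ambiguity codes are rejected)"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def dna_bases(self) -> str:
        """Bases normalized to the DNA alphabet (U -> T)."""
        return self.bases.replace("U", "T")

    def encoded(self) -> np.ndarray:
        """Sequence as an int8 array over the A=0,C=1,G=2,T=3 encoding."""
        return np.frombuffer(
            self.dna_bases.encode().translate(_ENCODE_TABLE), dtype=np.int8
        ).copy()

    def reverse_complement(self) -> "NucleicSeq":
        if self.alphabet != "DNA":
            raise ValueError("reverse_complement is defined for DNA sequences")
        rc = self.bases.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        return NucleicSeq(self.id + "_rc", "DNA", rc, self.description)


_ENCODE_TABLE = bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))


def encode_bases(seq: str) -> np.ndarray:
    """Encode an unambiguous DNA string (U allowed) as int8 codes."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _DNA_BASES
    if bad:
        raise ValueError(f"cannot encode bases {sorted(bad)}")
    return np.frombuffer(s.encode().translate(_ENCODE_TABLE), dtype=np.int8).copy()


def decode_bases(codes: np.ndarray) -> str:
    return "".join(_INDEX_BASE[c] for c in codes)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]


# --------------------------------------------------------------------------
# Hoogsteen pairing code
# --------------------------------------------------------------------------

def _rules_table(pairs: set[tuple[str, str]]) -> np.ndarray:
    table = np.zeros((4, 4), dtype=bool)
    for third, purine in pairs:
        table[_BASE_INDEX[third], _BASE_INDEX[purine]] = True
    return table


@dataclass(frozen=True)
class TriplexCode:
    """Allowed (third-strand base, duplex purine base) pairs for one motif.

    The rules are total over unambiguous bases: any (base, base) query has a
    defined boolean answer. ``orientation`` states how the third strand runs
    relative to the purine strand of the duplex.
    """

    motif: str
    orientation: str  # 'parallel' or 'antiparallel'
    table: np.ndarray = field(repr=False)

    def allowed(self, third_base: str, purine_base: str) -> bool:
        t = _normalize_base(third_base)
        p = _normalize_base(purine_base)
        return bool(self.table[_BASE_INDEX[t], _BASE_INDEX[p]])


#: Canonical triplex motifs. The reverse-Hoogsteen purine motif runs
#: antiparallel (G·G:C, A·A:T, T·A:T); the Hoogsteen pyrimidine motif runs
#: parallel (C·G:C, T/U·A:T); the mixed GT motif runs parallel (G·G:C, T·A:T).
TRIPLEX_CODES: dict[str, TriplexCode] = {
    "antiparallel_purine": TriplexCode(
        "antiparallel_purine", "antiparallel",
        _rules_table({("G", "G"), ("A", "A"), ("T", "A")}),
    ),
    "parallel_pyrimidine": TriplexCode(
        "parallel_pyrimidine", "parallel",
        _rules_table({("C", "G"), ("T", "A")}),
    ),
    "parallel_mixed": TriplexCode(
        "parallel_mixed", "parallel",
        _rules_table({("G", "G"), ("T", "A")}),
    ),
}

#: Motifs searched when the caller does not restrict them.
DEFAULT_MOTIFS = ("antiparallel_purine", "parallel_pyrimidine")

#: Search defaults: minimum triplex length (nt) and tolerated mismatch rate.
DEFAULT_MIN_LEN = 12
DEFAULT_MAX_ERROR_RATE = 0.2

_RATE_EPS = 1e-9  # absorbs float error in mismatches <= rate * length


def hoogsteen_allowed(third_base: str, purine_base: str, motif: str) -> bool:
    """Whether a third-strand base may pair with a duplex purine under `motif`.

    Bases are normalized to the DNA alphabet (U = T); ambiguity codes raise
    a ``ValueError``.
    """
    if motif not in TRIPLEX_CODES:
        raise ValueError(f"unknown motif {motif!r}; known: {sorted(TRIPLEX_CODES)}")
    return TRIPLEX_CODES[motif].allowed(third_base, purine_base)


# --------------------------------------------------------------------------
# Purine tract discovery
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PurineTract:
    """A maximal purine-rich interval, in plus-strand coordinates.

    ``strand`` is the strand carrying the purine run: '+' means the given
    sequence itself, '-' means its Watson-Crick complement.
    """

    start: int
    end: int
    strand: str
    n_interruptions: int

    def __len__(self) -> int:
        return self.end - self.start


def _purine_windows(is_purine: np.ndarray, min_len: int, budget: int):
    """Maximal purine-endpoint windows with <= budget pyrimidines inside."""
    n = len(is_purine)
    pyr = np.flatnonzero(~is_purine)
    out = set()
    p = len(pyr)
    if p <= budget:
        raw = [(0, n)]
    else:
        raw = []
        # window i holds exactly the pyrimidines pyr[i .. i+budget-1] (when
        # budget > 0) and extends to the neighbouring pyrimidines exclusive
        for i in range(p - budget + 1):
            lo = 0 if i == 0 else pyr[i - 1] + 1
            hi = n if i + budget >= p else pyr[i + budget]
            raw.append((lo, hi))
    for lo, hi in raw:
        # trim to purine endpoints
        while lo < hi and not is_purine[lo]:
            lo += 1
        while hi > lo and not is_purine[hi - 1]:
            hi -= 1
        if hi - lo >= min_len:
            out.add((lo, hi))
    # trimming can make one raw window contain another; keep maximal only
    wins = sorted(out)
    keep = []
    for lo, hi in wins:
        if any(l2 <= lo and h2 >= hi and (l2, h2) != (lo, hi) for l2, h2 in wins):
            continue
        keep.append((lo, hi))
    return keep


def purine_tracts(duplex_seq: NucleicSeq | str, min_len: int = DEFAULT_MIN_LEN,
                  max_pyrimidine_interruptions: int = 2) -> list[PurineTract]:
    """Candidate triplex target sites: maximal purine-rich intervals.

    The duplex is given as one strand; tracts are searched on it and on the
    implied complementary strand. A tract begins and ends on a purine,
    contains at most ``max_pyrimidine_interruptions`` pyrimidines, has
    length >= ``min_len`` and cannot be extended on either side without
    violating the interruption budget. Minus-strand tracts (purine run on
    the complement) are reported in plus-strand coordinates.
    """
    seq = duplex_seq.dna_bases if isinstance(duplex_seq, NucleicSeq) else duplex_seq
    codes = encode_bases(seq)
    n = len(codes)
    is_purine_plus = (codes == _BASE_INDEX["A"]) | (codes == _BASE_INDEX["G"])
    tracts: list[PurineTract] = []
    for strand, is_pur in (("+", is_purine_plus), ("-", ~is_purine_plus)):
        for lo, hi in _purine_windows(is_pur, min_len, max_pyrimidine_interruptions):
            n_int = int(np.count_nonzero(~is_pur[lo:hi]))
            tracts.append(PurineTract(lo, hi, strand, n_int))
    tracts.sort(key=lambda t: (t.start, t.end, t.strand))
    return tracts


# --------------------------------------------------------------------------
# Triplex hits
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TriplexHit:
    """One gapless TFO↔TTS match.

    ``tfo_start/tfo_end`` index the RNA (third strand) 5'->3';
    ``start/end`` are plus-strand duplex coordinates; ``strand`` marks which
    duplex strand carries the matched purine tract. ``score`` counts matched
    positions (length − mismatches).
    """

    tfo_id: str
    tfo_start: int
    tfo_end: int
    chrom: str
    start: int
    end: int
    strand: str
    orientation: str
    motif: str
    mismatches: int
    length: int
    score: int

    def __post_init__(self):
        if self.tfo_end - self.tfo_start != self.length or self.end - self.start != self.length:
            raise ValueError("triplex hits are collinear: both intervals must equal length")
        if self.score != self.length - self.mismatches:
            raise ValueError("score must equal matched positions")

    @property
    def name(self) -> str:
        """BED name field: tfo_id:tfo_start-tfo_end:motif."""
        return f"{self.tfo_id}:{self.tfo_start}-{self.tfo_end}:{self.motif}"


def _maximal_windows(match: np.ndarray, min_len: int, rate: float,
                     max_chunk_elems: int = 1 << 24):
    """All maximal valid windows on every diagonal of one match matrix.

    Returns tuples (i, j, length, mismatches); see ``_maximal_windows_batch``
    for the window semantics.
    """
    return [
        (i, j, L, mm)
        for _, i, j, L, mm in _maximal_windows_batch(
            match[None, :, :], np.array([match.shape[1]]), min_len, rate,
            max_chunk_elems)
    ]


def _maximal_windows_batch(match3: np.ndarray, n_true: np.ndarray,
                           min_len: int, rate: float,
                           max_chunk_elems: int = 1 << 24):
    """Maximal valid windows on every diagonal of a batch of match matrices.

    ``match3`` has shape (R, m, n_max) — one third-strand sequence scored
    against R duplex strands padded to a common width, with true widths in
    ``n_true``. A window is valid when it starts and ends on a match, has
    length >= min_len and mismatches <= rate*length; it is maximal when no
    valid window on the same diagonal strictly contains it. Diagonals from
    all matrices are processed in one vectorized pass. Returns tuples
    (r, i, j, length, mismatches) with (i, j) indexing (third strand,
    purine strand) of matrix r.
    """
    R, m, n_max = match3.shape
    K = min(m, n_max)
    if K < min_len:
        return []
    # per-matrix diagonal bookkeeping, concatenated
    rid_l, i0_l, j0_l, len_l = [], [], [], []
    for r in range(R):
        n = int(n_true[r])
        dvals = np.arange(-(m - 1), n)
        i0 = np.maximum(0, -dvals)
        j0 = np.maximum(0, dvals)
        len_d = np.minimum(m - i0, n - j0)
        ok = len_d >= min_len
        rid_l.append(np.full(int(ok.sum()), r))
        i0_l.append(i0[ok])
        j0_l.append(j0[ok])
        len_l.append(len_d[ok])
    rid0 = np.concatenate(rid_l)
    i00 = np.concatenate(i0_l)
    j00 = np.concatenate(j0_l)
    len0 = np.concatenate(len_l)
    if len(rid0) == 0:
        return []

    # any valid window carries at least this many matching positions
    min_matches = min_len - int(np.floor(rate * min_len + _RATE_EPS))

    results = []
    chunk = max(1, max_chunk_elems // (K * K + 1))
    for c0 in range(0, len(i00), chunk):
        rr = rid0[c0:c0 + chunk]
        ii, jj, ll = i00[c0:c0 + chunk], j00[c0:c0 + chunk], len0[c0:c0 + chunk]
        nd = len(ii)
        pos = np.arange(K)
        I = ii[:, None] + pos[None, :]
        J = jj[:, None] + pos[None, :]
        inside = pos[None, :] < ll[:, None]
        D = np.zeros((nd, K), dtype=bool)
        np.copyto(
            D,
            match3[rr[:, None], np.minimum(I, m - 1), np.minimum(J, n_max - 1)],
            where=inside,
        )
        Dv = D & inside

        # cheap per-diagonal prefilter on total match count
        enough = Dv.sum(axis=1) >= min_matches
        if not enough.any():
            continue
        rr, ii, jj, ll = rr[enough], ii[enough], jj[enough], ll[enough]
        D, Dv, inside = D[enough], Dv[enough], inside[enough]
        nd = len(ii)

        # prefix mismatch counts: Pm[d, x] = mismatches among first x positions
        mism = inside & ~D
        Pm = np.zeros((nd, K + 1), dtype=np.int32)
        np.cumsum(mism, axis=1, out=Pm[:, 1:])
        g = Pm - rate * np.arange(K + 1)[None, :]

        lidx = np.arange(K)
        ridx = np.arange(1, K + 1)
        length_ok = (ridx[None, :] - lidx[:, None]) >= min_len
        # valid[d, l, r-1]: start on match, end on match, ratio constraint
        valid = (
            Dv[:, :, None]
            & Dv[:, None, :]
            & length_ok[None, :, :]
            & (g[:, 1:][:, None, :] <= g[:, :K][:, :, None] + _RATE_EPS)
        )
        rev = valid[:, :, ::-1]
        rev_arg = rev.argmax(axis=2)
        anyv = np.take_along_axis(rev, rev_arg[:, :, None], axis=2)[:, :, 0]
        rmax = np.where(anyv, K - rev_arg, 0)  # window end r, 0 if none

        # left-maximality: drop l if some l' < l reaches an end >= ours
        prevmax = np.zeros_like(rmax)
        np.maximum.accumulate(rmax[:, :-1], axis=1, out=prevmax[:, 1:])
        keep = anyv & (rmax > prevmax)

        for d, l in zip(*np.nonzero(keep)):
            r = int(rmax[d, l])
            results.append((
                int(rr[d]), int(ii[d] + l), int(jj[d] + l), r - int(l),
                int(Pm[d, r] - Pm[d, l]),
            ))
    return results


def find_tts(tfo: NucleicSeq, duplex: NucleicSeq,
             min_len: int = DEFAULT_MIN_LEN,
             max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
             motifs: tuple[str, ...] = DEFAULT_MOTIFS) -> list[TriplexHit]:
    """All maximal triplex matches between a TFO and a duplex DNA sequence.

    The duplex is given as its plus strand; both it and the implied
    complementary strand are searched as potential purine strands, under
    every enabled motif (each motif fixes the third-strand orientation).
    Same-motif, same-strand hits that overlap on both the RNA and the DNA
    side are collapsed to the highest-scoring one, ties broken by leftmost
    DNA then leftmost RNA coordinate. Hits are sorted by (chrom, start,
    tfo_start).
    """
    return find_tts_many(tfo, [duplex], min_len, max_error_rate, motifs)[0]


def find_tts_many(tfo: NucleicSeq, duplexes,
                  min_len: int = DEFAULT_MIN_LEN,
                  max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
                  motifs: tuple[str, ...] = DEFAULT_MOTIFS,
                  merge: bool = True) -> list[list[TriplexHit]]:
    """``find_tts`` of one TFO against many duplexes in one vectorized pass.

    Equivalent to ``[find_tts(tfo, d, ...) for d in duplexes]`` but far
    cheaper for many short duplexes (the randomization null re-scans
    hundreds of region sets): diagonals of all duplexes are enumerated
    together. Returns one hit list per input duplex.
    """
    duplexes = list(duplexes)
    for duplex in duplexes:
        if duplex.alphabet != "DNA":
            raise ValueError("duplex must be a DNA sequence")
    for motif in motifs:
        if motif not in TRIPLEX_CODES:
            raise ValueError(f"unknown motif {motif!r}")
    m = len(tfo)
    if not duplexes:
        return []
    if min_len > m:
        warnings.warn(
            f"min_len={min_len} exceeds TFO length {m}; no hits possible",
            stacklevel=2,
        )
        return [[] for _ in duplexes]

    t_fwd = tfo.encoded()
    R = len(duplexes)
    n_true = np.array([len(d) for d in duplexes])
    n_max = int(n_true.max())
    plus = np.zeros((R, n_max), dtype=np.int8)
    minus = np.zeros((R, n_max), dtype=np.int8)
    for r, duplex in enumerate(duplexes):
        s = duplex.encoded()
        plus[r, :len(s)] = s
        minus[r, :len(s)] = _COMPLEMENT[s][::-1]

    per_duplex: list[list[TriplexHit]] = [[] for _ in duplexes]
    for motif in motifs:
        code = TRIPLEX_CODES[motif]
        t_arr = t_fwd if code.orientation == "parallel" else t_fwd[::-1]
        lut = code.table[t_arr]  # (m, 4)
        for strand, strands_arr in (("+", plus), ("-", minus)):
            match3 = np.transpose(lut[:, strands_arr], (1, 0, 2))  # (R, m, n_max)
            for r, ti, pj, length, mism in _maximal_windows_batch(
                    match3, n_true, min_len, max_error_rate):
                n = int(n_true[r])
                if code.orientation == "parallel":
                    tfo_start, tfo_end = ti, ti + length
                else:
                    tfo_start, tfo_end = m - (ti + length), m - ti
                if strand == "+":
                    start, end = pj, pj + length
                else:
                    start, end = n - (pj + length), n - pj
                per_duplex[r].append(TriplexHit(
                    tfo_id=tfo.id, tfo_start=tfo_start, tfo_end=tfo_end,
                    chrom=duplexes[r].id, start=start, end=end, strand=strand,
                    orientation=code.orientation, motif=motif,
                    mismatches=mism, length=length, score=length - mism,
                ))
    if not merge:
        return [sorted(hits, key=lambda h: (h.chrom, h.start, h.tfo_start,
                                            h.motif, h.strand))
                for hits in per_duplex]
    return [merge_hits(hits) for hits in per_duplex]


def merge_hits(hits: list[TriplexHit]) -> list[TriplexHit]:
    """Collapse same-motif, same-strand hits overlapping on both sides.

    The highest-scoring hit of each overlap group is retained; ties are
    broken by leftmost DNA coordinate then leftmost RNA coordinate. The
    result is sorted by (chrom, start, tfo_start).
    """
    kept: list[TriplexHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.chrom, h.start, h.tfo_start,
                                         h.end, h.tfo_end, h.motif, h.strand)):
        absorbed = any(
            k.motif == h.motif and k.strand == h.strand and k.chrom == h.chrom
            and k.start < h.end and h.start < k.end
            and k.tfo_start < h.tfo_end and h.tfo_start < k.tfo_end
            for k in kept
        )
        if not absorbed:
            kept.append(h)
    kept.sort(key=lambda h: (h.chrom, h.start, h.tfo_start, h.motif, h.strand))
    return kept
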