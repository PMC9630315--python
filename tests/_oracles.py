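"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain enumeration, sharing no
code path with the package implementation it checks.
"""

from __future__ import annotations

import math

from triplexkit.triplex import (
    TRIPLEX_CODES, TriplexHit, NucleicSeq, merge_hits, reverse_complement,
)


def brute_force_hits(tfo: NucleicSeq, duplex: NucleicSeq, min_len: int,
                     rate: float, motifs) -> list[TriplexHit]:
    """Every maximal mismatch-bounded window by exhaustive enumeration."""
    m, n = len(tfo), len(duplex)
    t_norm = tfo.dna_bases
    hits = []
    for motif in motifs:
        code = TRIPLEX_CODES[motif]
        T = t_norm if code.orientation == "parallel" else t_norm[::-1]
        for strand, P in (("+", duplex.dna_bases),
                          ("-", reverse_complement(duplex.dna_bases))):
            valid = []
            for i in range(m):
                for j in range(n):
                    for L in range(min_len, min(m - i, n - j) + 1):
                        pairs = [code.allowed(T[i + k], P[j + k]) for k in range(L)]
                        if not (pairs[0] and pairs[-1]):
                            continue
                        mism = L - sum(pairs)
                        if mism <= rate * L + 1e-9:
                            valid.append((i, j, L, mism))
            for (i, j, L, mism) in valid:
                contained = any(
                    (j2 - i2) == (j - i) and i2 <= i and i2 + L2 >= i + L and L2 > L
                    for (i2, j2, L2, _) in valid
                )
                if contained:
                    continue
                if code.orientation == "parallel":
                    ts, te = i, i + L
                else:
                    ts, te = m - (i + L), m - i
                if strand == "+":
                    ds, de = j, j + L
                else:
                    ds, de = n - (j + L), n - j
                hits.append(TriplexHit(tfo.id, ts, te, duplex.id, ds, de, strand,
                                       code.orientation, motif, mism, L, L - mism))
    return merge_hits(hits)


def brute_force_purine_tracts(seq: str, min_len: int, budget: int):
    """All maximal purine-endpoint intervals by substring enumeration.

    Returns sorted (start, end, strand) tuples in plus coordinates.
    """
    out = []
    for strand in "+-":
        if strand == "+":
            is_pur = [b in "AG" for b in seq]
        else:
            is_pur = [b in "CT" for b in seq]  # purine on the complement
        n = len(seq)
        valid = [
            (i, j)
            for i in range(n)
            for j in range(i + min_len, n + 1)
            if is_pur[i] and is_pur[j - 1]
            and sum(not p for p in is_pur[i:j]) <= budget
        ]
        for i, j in valid:
            if not any(i2 <= i and j2 >= j and (i2, j2) != (i, j) for i2, j2 in valid):
                out.append((i, j, strand))
    return sorted(out)


def poisson_tail_neg_log10(observed: int, lam: float, terms: int = 4000) -> float:
    """-log10 P(X >= observed) by direct log-space term summation."""
    if observed == 0:
        return 0.0
    logs = [
        k * math.log(lam) - lam - math.lgamma(k + 1)
        for k in range(observed, observed + terms)
    ]
    mx = max(logs)
    total = mx + math.log(sum(math.exp(x - mx) for x in logs))
    return -total / math.log(10)
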