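"""Independent brute-force oracles used by the test suite.

These are deliberately written from scratch, without reusing the package's
implementations: full Smith-Waterman dynamic programming, pathway-enumeration
Nei-Gojobori counting (via Biopython's translation), and a longest-common-
substring DP.
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# Smith-Waterman (full DP, linear gap cost)
# ---------------------------------------------------------------------------

def smith_waterman_score(a: str, b: str, match: int, mismatch: int, gap: int) -> int:
    """Optimal local alignment score; gaps cost ``gap`` per column."""
    prev = [0] * (len(b) + 1)
    best = 0
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            diag = prev[j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            cur[j] = max(0, diag, prev[j] - gap, cur[j - 1] - gap)
            if cur[j] > best:
                best = cur[j]
        prev = cur
    return best


def smith_waterman_alignment(a: str, b: str, match: int, mismatch: int, gap: int):
    """(score, aligned column list) of one optimal local alignment.

    Columns are (i, j) index pairs for substitution columns and (i, None) /
    (None, j) for gaps, 0-based.
    """
    H = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            diag = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            H[i][j] = max(0, diag, H[i - 1][j] - gap, H[i][j - 1] - gap)
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    cols = []
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0:
        diag = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
        if H[i][j] == diag:
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] - gap:
            cols.append((i - 1, None))
            i -= 1
        else:
            cols.append((None, j - 1))
            j -= 1
    cols.reverse()
    return best, cols


# ---------------------------------------------------------------------------
# Nei-Gojobori brute force
# ---------------------------------------------------------------------------

def ng_sites(codon: str) -> tuple[float, float]:
    aa = translate(codon)
    syn = 0
    for pos, base in itertools.product(range(3), "ACGT"):
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if alt not in STOPS and translate(alt) == aa:
            syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def ng_pathways(ca: str, cb: str) -> tuple[float, float]:
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    kept, all_paths = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, bad = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                bad = True
            if translate(cur) == translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not bad:
            kept.append((sd, nd))
    use = kept or all_paths
    return (sum(p[0] for p in use) / len(use), sum(p[1] for p in use) / len(use))


def ng_pair(seq_a: str, seq_b: str) -> dict:
    """Full-enumeration Nei-Gojobori with Jukes-Cantor correction."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if ("-" in ca or "-" in cb or "N" in ca or "N" in cb
                or ca in STOPS or cb in STOPS):
            continue
        sa, na = ng_sites(ca)
        sb, nb = ng_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = ng_pathways(ca, cb)
        Sd += sd
        Nd += nd
    ps, pn = Sd / S, Nd / N
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "ps": ps, "pn": pn,
            "Ks": jc(ps), "Ka": jc(pn)}


# ---------------------------------------------------------------------------
# longest common substring
# ---------------------------------------------------------------------------

def longest_common_substring(a: str, b: str) -> int:
    prev = [0] * (len(b) + 1)
    best = 0
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best
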