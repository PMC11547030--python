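"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles against the
stated definitions (direct enumeration, quadratic scans, match matrices) and
shares no code with the package internals beyond the NCBI code tables that
both sides take from Biopython.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations

import numpy as np
from Bio.Data import CodonTable

_BASES = "ACGT"
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# Nei-Gojobori by direct enumeration


def _code(table_id: int):
    t = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(t.forward_table), set(t.stop_codons)


def _syn_sites(codon: str, fwd: dict, stops: set) -> float:
    s = 0.0
    for pos in range(3):
        syn = 0
        for nb in _BASES:
            if nb == codon[pos]:
                continue
            mutant = codon[:pos] + nb + codon[pos + 1 :]
            if mutant not in stops and fwd[mutant] == fwd[codon]:
                syn += 1
        s += syn / 3.0
    return s


def _diffs(c1: str, c2: str, fwd: dict, stops: set) -> tuple[float, float]:
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0

    def walk(order, count_stop_steps):
        cur, sd, nd = c1, 0, 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in stops and not count_stop_steps:
                return None
            if (
                cur not in stops
                and nxt not in stops
                and fwd[cur] == fwd[nxt]
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [r for r in (walk(o, False) for o in permutations(positions)) if r]
    if not results:
        results = [walk(o, True) for o in permutations(positions)]
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def ng_oracle(seq_a: str, seq_b: str, table_id: int = 5) -> tuple[float, float]:
    """(Ka, Ks) by exhaustive per-codon pathway enumeration."""
    fwd, stops = _code(table_id)
    s_a = s_b = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if any(b not in _BASES for b in ca + cb):
            continue
        if ca in stops or cb in stops:
            continue
        n_codons += 1
        s_a += _syn_sites(ca, fwd, stops)
        s_b += _syn_sites(cb, fwd, stops)
        d_s, d_n = _diffs(ca, cb, fwd, stops)
        sd += d_s
        nd += d_n
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * n_codons - s_sites

    def jc(p):
        return math.nan if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    ks = jc(sd / s_sites) if s_sites > 0 else 0.0
    ka = jc(nd / n_sites) if n_sites > 0 else 0.0
    return ka, ks


# ---------------------------------------------------------------------------
# SSRs by quadratic scan


def _primitive(motif: str) -> bool:
    return all(
        not (len(motif) % p == 0 and motif == motif[:p] * (len(motif) // p))
        for p in range(1, len(motif))
    )


def _min_rot(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def brute_ssrs(seq: str, minima=(10, 5, 4, 3, 3, 3)) -> list[tuple]:
    """All (motif, reps, start, end) perfect SSRs, by direct position scan."""
    n = len(seq)
    out = []
    for p in range(1, len(minima) + 1):
        thr = minima[p - 1]
        for i in range(n - p):
            if i > 0 and seq[i - 1] == seq[i + p - 1]:
                continue  # periodic run extends left: i is not its start
            m = 0
            while i + p + m < n and seq[i + m] == seq[i + p + m]:
                m += 1
            if m == 0:
                continue
            reps = (m + p) // p
            motif = seq[i : i + p]
            if reps >= thr and _primitive(motif):
                out.append((_min_rot(motif), reps, i + 1, i + reps * p))
    return sorted(out, key=lambda t: (t[2], len(t[0])))


# ---------------------------------------------------------------------------
# Dispersed repeats via match matrices


def _runs(mask: np.ndarray):
    """(start, length) of maximal True runs of a 1-D boolean array."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends - starts))


def brute_dispersed(seq: str, min_len: int = 30) -> set[tuple]:
    """{(kind, length, pos_a, pos_b)} of maximal exact repeat pairs.

    Builds the full pairwise match matrix for each orientation class and
    reads maximal runs off its (anti)diagonals.
    """
    s = np.frombuffer(seq.encode(), dtype="S1")
    n = len(seq)
    comp = np.frombuffer("".join(_COMP[b] for b in seq).encode(), dtype="S1")
    results: set[tuple] = set()

    # parallel classes: runs along diagonals of the match matrix
    for kind, left in (("forward", s), ("complementary", comp)):
        m = left[:, None] == s[None, :]
        for off in range(-(n - min_len), n - min_len + 1):
            diag = np.diagonal(m, offset=off)
            for start, length in _runs(diag):
                if length < min_len:
                    continue
                i = start - min(0, off)  # row index
                j = i + off
                if kind == "forward" and j <= i:
                    continue
                if kind == "complementary" and i == j:
                    continue
                a, b = sorted((i, j))
                results.add((kind, length, a + 1, b + 1))

    # antiparallel classes: runs along anti-diagonals
    for kind, left in (("palindromic", comp), ("reverse", s)):
        m = left[:, None] == s[None, ::-1]  # column j corresponds to n-1-j
        for off in range(-(n - min_len), n - min_len + 1):
            diag = np.diagonal(m, offset=off)
            for start, length in _runs(diag):
                if length < min_len:
                    continue
                i = start - min(0, off)  # row: start of copy1
                jj = i + off  # flipped column
                j_end = n - 1 - jj  # real column of the run's first element
                b = j_end - length + 1  # start of copy2
                a, bb = sorted((i, b))
                if kind == "reverse" and a == bb:
                    continue
                results.add((kind, length, a + 1, bb + 1))
    return results


# ---------------------------------------------------------------------------
# Stem-loop candidates by triple loop


def brute_stem_loops(seq: str, min_stem: int = 5, max_loop: int = 50) -> set[tuple]:
    """{(stem_start, stem_len, loop_len)}: maximal inverted-repeat arms."""
    n = len(seq)
    out = set()
    for left_end in range(n):  # last base of the left arm (0-based)
        for loop in range(0, max_loop + 1):
            right_start = left_end + 1 + loop
            if right_start >= n:
                break
            k = 0
            while (
                left_end - k >= 0
                and right_start + k < n
                and _COMP.get(seq[left_end - k]) == seq[right_start + k]
            ):
                k += 1
            if k < min_stem:
                continue
            # innermost: the base pair just inside must not pair
            if loop >= 2 and _COMP.get(seq[left_end + 1]) == seq[right_start - 1]:
                continue
            out.add((left_end - k + 2, k, loop))
    return out
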