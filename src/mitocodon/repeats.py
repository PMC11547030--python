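"""Repeat detection: microsatellites, dispersed repeats, tandem units, stem-loops.

* :func:`find_ssrs` reports perfect simple sequence repeats (motif 1-6 nt)
  at the conventional minimum repeat numbers (10, 5, 4, 3, 3, 3 for mono-
  through hexanucleotide motifs).  Only maximal runs with a primitive motif
  are reported, so an (A)10 run is never double-reported as (AA)5.
* :func:`find_dispersed` finds maximal exact repeat pairs of at least 30 bp
  in the four orientation classes: forward (direct copy), reverse (reversed
  copy), complementary (complemented, unreversed copy) and palindromic
  (reverse-complemented copy, i.e. an inverted repeat).
* :func:`decompose_tandem` segments a non-coding region into tandem repeat
  units by exact-match autocorrelation, labelling unit types by order of
  first occurrence (I, II, ...).
* :func:`stem_loop_candidates` lists inverted-repeat pairs that could form
  stem-loops; purely combinatorial, no thermodynamic folding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .genome_model import reverse_complement

__all__ = [
    "SSR",
    "DispersedRepeat",
    "TandemDecomposition",
    "find_ssrs",
    "find_dispersed",
    "decompose_tandem",
    "stem_loop_candidates",
]

DEFAULT_SSR_MINIMA = (10, 5, 4, 3, 3, 3)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def _min_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_primitive(motif: str) -> bool:
    """True if the motif is not itself a repetition of a shorter unit."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


@dataclass(frozen=True)
class SSR:
    motif: str  # lexicographically minimal rotation
    n_repeats: int
    start: int  # 1-based inclusive
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def find_ssrs(
    seq: str,
    min_repeats: tuple[int, ...] = DEFAULT_SSR_MINIMA,
    circular: bool = False,
) -> list[SSR]:
    """Perfect SSRs of motif length 1..len(min_repeats).

    Only full repeat units are reported (region length = motif length x
    repeat count) and only for maximal, non-extendable runs whose motif is
    primitive.  With ``circular=True`` the sequence is doubled so runs
    crossing the origin are found, then de-duplicated by modular position.
    """
    seq = seq.upper()
    n = len(seq)
    scan = seq + seq if circular else seq
    found: dict[tuple[int, int], SSR] = {}
    for p in range(1, len(min_repeats) + 1):
        threshold = min_repeats[p - 1]
        i = 0
        while i + p < len(scan):
            if scan[i] != scan[i + p]:
                i += 1
                continue
            j = i
            while j + p < len(scan) and scan[j + p] == scan[j]:
                j += 1
            run_len = j - i + p  # maximal stretch with period p
            reps = run_len // p
            motif = scan[i : i + p]
            if reps >= threshold and _is_primitive(motif):
                start = i + 1
                if not circular or start <= n:
                    if circular and run_len > n:
                        reps = n // p  # cap a run covering the whole circle
                    end = start + reps * p - 1
                    key = (((start - 1) % n) + 1, p)
                    if key not in found:
                        found[key] = SSR(
                            motif=_min_rotation(motif),
                            n_repeats=reps,
                            start=start,
                            end=end,
                        )
            i = j + 1
    return sorted(found.values(), key=lambda s: (s.start, len(s.motif)))


@dataclass(frozen=True)
class DispersedRepeat:
    kind: str  # forward | reverse | palindromic | complementary
    length: int
    pos_a: int  # 1-based start of first copy
    pos_b: int  # 1-based start of second copy

    def copies(self, seq: str) -> tuple[str, str]:
        return (
            seq[self.pos_a - 1 : self.pos_a - 1 + self.length],
            seq[self.pos_b - 1 : self.pos_b - 1 + self.length],
        )

    def verify(self, seq: str) -> bool:
        """Direct string check of the class relation (self-checking output)."""
        a, b = self.copies(seq)
        if self.kind == "forward":
            return a == b
        if self.kind == "reverse":
            return b == a[::-1]
        if self.kind == "complementary":
            return b == _complement(a)
        if self.kind == "palindromic":
            return b == reverse_complement(a)
        raise ValueError(self.kind)


def _seed_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def find_dispersed(seq: str, min_len: int = 30) -> list[DispersedRepeat]:
    """Maximal exact repeat pairs >= min_len in the four orientation classes.

    Seed-and-extend on min_len-mers; every reported repeat re-verifies its
    class relation by direct string comparison before being returned.
    """
    seq = seq.upper()
    n = len(seq)
    if n < min_len:
        raise ValueError(f"sequence shorter than min_len={min_len}")
    k = min_len
    index = _seed_positions(seq, k)
    results: set[DispersedRepeat] = set()

    def comp(b: str) -> str:
        return _complement(b)

    # --- parallel classes: forward and complementary -----------------------
    for kind, transform in (("forward", None), ("complementary", comp)):
        for a in range(n - k + 1):
            kmer = seq[a : a + k]
            key = _complement(kmer) if transform else kmer
            for b in index.get(key, ()):
                if kind == "forward" and b <= a:
                    continue
                if kind == "complementary" and b == a:
                    continue
                # extend left/right in parallel
                la, lb = a, b
                while la > 0 and lb > 0 and (
                    seq[lb - 1] == (comp(seq[la - 1]) if transform else seq[la - 1])
                ):
                    la -= 1
                    lb -= 1
                ra, rb = a + k, b + k
                while ra < n and rb < n and (
                    seq[rb] == (comp(seq[ra]) if transform else seq[ra])
                ):
                    ra += 1
                    rb += 1
                length = ra - la
                pa, pb = sorted((la, lb))
                if kind == "complementary" and pb < pa:
                    pa, pb = pb, pa
                results.add(
                    DispersedRepeat(kind=kind, length=length, pos_a=pa + 1, pos_b=pb + 1)
                )

    # --- antiparallel classes: palindromic and reverse ---------------------
    # copy2[i] relates to copy1[L-1-i]; extending copy1 rightward extends
    # copy2 leftward.
    for kind in ("palindromic", "reverse"):
        for a in range(n - k + 1):
            kmer = seq[a : a + k]
            key = reverse_complement(kmer) if kind == "palindromic" else kmer[::-1]
            for b in index.get(key, ()):
                la, rb = a, b + k  # extend left of copy1 with right of copy2
                while la > 0 and rb < n and (
                    seq[rb] == (comp(seq[la - 1]) if kind == "palindromic" else seq[la - 1])
                ):
                    la -= 1
                    rb += 1
                ra, lb = a + k, b  # extend right of copy1 with left of copy2
                while ra < n and lb > 0 and (
                    seq[lb - 1] == (comp(seq[ra]) if kind == "palindromic" else seq[ra])
                ):
                    ra += 1
                    lb -= 1
                length = ra - la
                pa, pb = sorted((la, lb))
                if pa == pb and kind == "reverse":
                    continue  # a self-reverse (even palindrome in plain sense)
                results.add(
                    DispersedRepeat(kind=kind, length=length, pos_a=pa + 1, pos_b=pb + 1)
                )

    out = sorted(
        (r for r in results if r.length >= min_len),
        key=lambda r: (r.kind, r.pos_a, r.pos_b),
    )
    for r in out:
        assert r.verify(seq), f"internal error: {r} fails its class relation"
    return out


@dataclass
class TandemDecomposition:
    region: str
    units: list[tuple[str, int, int, int]]  # (unit_type, start, end, length)
    unit_consensus: dict[str, str]

    @property
    def order_string(self) -> str:
        return "-".join(u[0] for u in self.units)


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def _identity(a: str, b: str) -> float:
    if not a or len(a) != len(b):
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def decompose_tandem(
    region_seq: str,
    max_unit: int = 200,
    min_units: int = 2,
    region: str = "region",
    min_identity: float = 0.8,
) -> TandemDecomposition:
    """Greedy tandem-unit decomposition of a (non-coding) region.

    The principal period is the smallest lag whose exact-match
    autocorrelation over the self-overlap reaches ``min_identity`` (lags up
    to twice ``max_unit`` are scanned so alternating two-unit arrangements
    are caught).  If the trailing partial unit matches a prefix of the full
    period, the period is split there into two unit types, which turns an
    (AB)x(A) arrangement into the alternating decomposition I-II-I-II-I.
    No periodicity found is a valid outcome and yields an empty
    decomposition.
    """
    s = region_seq.upper()
    n = len(s)
    min_overlap = 20
    best: Optional[int] = None
    for lag in range(1, min(2 * max_unit, n - min_overlap) + 1):
        if n // lag < min_units:
            break
        overlap = n - lag
        matches = sum(s[i] == s[i + lag] for i in range(overlap))
        if matches / overlap >= min_identity:
            best = lag
            break
    if best is None:
        return TandemDecomposition(region=region, units=[], unit_consensus={})

    p = best
    k = n // p
    r = n - k * p
    unit = s[:p]
    units: list[tuple[str, int, int, int]] = []
    consensus: dict[str, str] = {}
    split = r if (r >= 10 and _identity(s[k * p :], unit[:r]) >= min_identity) else 0
    if split:
        type_a, type_b = _ROMAN[0], _ROMAN[1]
        consensus[type_a] = unit[:split]
        consensus[type_b] = unit[split:]
        for i in range(k):
            base = i * p
            units.append((type_a, base + 1, base + split, split))
            units.append((type_b, base + split + 1, base + p, p - split))
        units.append((type_a, k * p + 1, n, r))
    else:
        consensus[_ROMAN[0]] = unit
        for i in range(k):
            base = i * p
            units.append((_ROMAN[0], base + 1, base + p, p))
    return TandemDecomposition(region=region, units=units, unit_consensus=consensus)


def stem_loop_candidates(
    region_seq: str, min_stem: int = 5, max_loop: int = 50
) -> list[tuple[int, int, int]]:
    """Inverted-repeat stem-loop candidates: (stem_start, stem_len, loop_len).

    A candidate is a maximal pair of arms ``seq[l-k+1..l]`` /
    ``seq[r..r+k-1]`` with the right arm equal to the reverse complement of
    the left, separated by a loop of 0..max_loop bases.  Arms are grown
    outward from every innermost base pair; only non-extendable stems of at
    least ``min_stem`` pairs are reported.  ``stem_start`` is the 1-based
    start of the left arm.
    """
    s = region_seq.upper()
    n = len(s)
    pair = {"A": "T", "T": "A", "G": "C", "C": "G"}
    out = []
    for l in range(n - 1):
        for r in range(l + 1, min(n, l + max_loop + 2)):
            if pair.get(s[l]) != s[r]:
                continue
            # innermost pair: the next inward positions must not pair
            if r - l >= 3 and pair.get(s[l + 1]) == s[r - 1]:
                continue
            k = 1
            while l - k >= 0 and r + k < n and pair.get(s[l - k]) == s[r + k]:
                k += 1
            if k >= min_stem:
                out.append((l - k + 2, k, r - l - 1))  # 1-based left-arm start
    return sorted(set(out))
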