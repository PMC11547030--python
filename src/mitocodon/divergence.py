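"""Pairwise Ka/Ks (Nei-Gojobori 1986) and sliding-window nucleotide diversity.

The Ka/Ks estimator is the classical counting method: per-codon synonymous
site fractions are derived from the genetic code (each codon position
contributes the fraction of its three possible changes that are synonymous;
changes creating a stop codon count as nonsynonymous, so synonymous and
nonsynonymous sites always sum to 3 per codon); codons differing at several
positions are averaged over all minimal mutational pathways with equal
weight, excluding pathways that pass through a stop codon (falling back to
all pathways if every one is blocked); the raw proportions are corrected for
multiple hits with the Jukes-Cantor formula ``d = -3/4 ln(1 - 4p/3)``.

Codons containing a gap or N in either sequence are wholly excluded from
both the site and the difference counts (pairwise deletion).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .codon_usage import INVERTEBRATE_MITO, GeneticCode

__all__ = [
    "CodonAlignment",
    "PairwiseRates",
    "DiversitySeries",
    "nei_gojobori",
    "gene_rate_matrix",
    "GeneRates",
    "sliding_pi",
]

_BASES = "ACGT"


@dataclass
class CodonAlignment:
    """Equal-length, in-frame, gapped nucleotide rows for one gene."""

    gene: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if self.rows and len(self.rows[0]) % 3 != 0:
            raise ValueError("alignment length is not a multiple of 3")
        self.rows = [r.upper().replace("U", "T") for r in self.rows]

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0


@dataclass
class PairwiseRates:
    taxon_a: str
    taxon_b: str
    ka: float  # substitutions per nonsynonymous site
    ks: float  # substitutions per synonymous site
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float

    @property
    def omega(self) -> Optional[float]:
        """Ka/Ks; None when Ks == 0 (or either distance is undefined)."""
        if math.isnan(self.ka) or math.isnan(self.ks) or self.ks == 0:
            return None
        return self.ka / self.ks


def _syn_site_fraction(codon: str, code: GeneticCode) -> float:
    """Synonymous sites of one sense codon (0..3)."""
    aa = code.codon_to_aa[codon]
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if not code.is_stop(mutant) and code.codon_to_aa[mutant] == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def _codon_sites(codon: str, table_id: int) -> tuple[float, float]:
    code = GeneticCode.from_ncbi(table_id)
    s = _syn_site_fraction(codon, code)
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pathway_diffs(c1: str, c2: str, table_id: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Averaged with equal weight over all orderings of the differing
    positions; orderings whose intermediate codons are stops are excluded
    unless that removes every pathway.
    """
    code = GeneticCode.from_ncbi(table_id)
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways: list[tuple[float, float, bool]] = []  # (syn, nonsyn, has_stop)
    for order in permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code.is_stop(nxt):
                blocked = True
                syn = nonsyn = math.nan
                break
            if code.codon_to_aa[cur] == code.codon_to_aa[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        pathways.append((syn, nonsyn, blocked))
    open_paths = [(s, n) for s, n, blocked in pathways if not blocked]
    if not open_paths:
        # every route passes a stop: fall back to equal weighting over all,
        # counting the step into/out of a stop as nonsynonymous
        open_paths = []
        for order in permutations(diff_pos):
            cur = c1
            syn = nonsyn = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if (
                    not code.is_stop(cur)
                    and not code.is_stop(nxt)
                    and code.codon_to_aa[cur] == code.codon_to_aa[nxt]
                ):
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            open_paths.append((syn, nonsyn))
    syn = sum(p[0] for p in open_paths) / len(open_paths)
    nonsyn = sum(p[1] for p in open_paths) / len(open_paths)
    return syn, nonsyn


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; nan (flagged) when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        warnings.warn(f"proportion {p:.3f} >= 3/4; Jukes-Cantor correction undefined")
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _valid_codon(codon: str) -> bool:
    return all(b in _BASES for b in codon)


def nei_gojobori(
    seq_a: str,
    seq_b: str,
    code: GeneticCode = INVERTEBRATE_MITO,
    taxon_a: str = "a",
    taxon_b: str = "b",
) -> PairwiseRates:
    """Nei-Gojobori Ka/Ks between two equal-length in-frame sequences."""
    seq_a = seq_a.upper().replace("U", "T")
    seq_b = seq_b.upper().replace("U", "T")
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if len(seq_a) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    tid = code.table_id
    s_sites_a = s_sites_b = 0.0
    sd = nd = 0.0
    n_codons_used = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (_valid_codon(ca) and _valid_codon(cb)):
            continue  # pairwise deletion of gap/N codons
        if code.is_stop(ca) or code.is_stop(cb):
            warnings.warn(f"stop codon at codon {i // 3 + 1}; codon excluded")
            continue
        n_codons_used += 1
        sa, _ = _codon_sites(ca, tid)
        sb, _ = _codon_sites(cb, tid)
        s_sites_a += sa
        s_sites_b += sb
        ds, dn = _pathway_diffs(ca, cb, tid)
        sd += ds
        nd += dn
    if n_codons_used == 0:
        raise ValueError("no comparable codons")
    s_sites = (s_sites_a + s_sites_b) / 2.0
    n_sites = 3.0 * n_codons_used - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return PairwiseRates(
        taxon_a=taxon_a,
        taxon_b=taxon_b,
        ka=jukes_cantor(pn),
        ks=jukes_cantor(ps),
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
        syn_diffs=sd,
        nonsyn_diffs=nd,
    )


@dataclass
class GeneRates:
    gene: str
    pairs: list[PairwiseRates]
    mean_omega: Optional[float]
    paired_t: Optional[float]  # paired t statistic of Ka vs Ks across pairs
    paired_p: Optional[float]


def gene_rate_matrix(alignments: Iterable[CodonAlignment]) -> list[GeneRates]:
    """All unordered pairwise rates per gene, with a Ka-vs-Ks paired t-test."""
    out: list[GeneRates] = []
    for aln in alignments:
        if len(aln.taxa) < 2:
            warnings.warn(f"gene {aln.gene}: fewer than 2 taxa; skipped")
            continue
        pairs = [
            nei_gojobori(aln.rows[i], aln.rows[j], taxon_a=aln.taxa[i], taxon_b=aln.taxa[j])
            for i, j in combinations(range(len(aln.taxa)), 2)
        ]
        omegas = [p.omega for p in pairs if p.omega is not None]
        mean_omega = sum(omegas) / len(omegas) if omegas else None
        kas = [p.ka for p in pairs if not (math.isnan(p.ka) or math.isnan(p.ks))]
        kss = [p.ks for p in pairs if not (math.isnan(p.ka) or math.isnan(p.ks))]
        if len(kas) >= 2 and np.ptp(np.asarray(kas) - np.asarray(kss)) > 0:
            t, p = stats.ttest_rel(kas, kss)
        else:
            t = p = None
        out.append(
            GeneRates(gene=aln.gene, pairs=pairs, mean_omega=mean_omega, paired_t=t, paired_p=p)
        )
    return out


# ---------------------------------------------------------------------------
# Sliding-window nucleotide diversity


@dataclass
class DiversitySeries:
    """Windowed nucleotide diversity (pi) along an alignment.

    ``pi[i]`` is the mean over sequence pairs of (differences / compared
    sites) inside window *i*; sites with a gap or ambiguity in either row of
    a pair are excluded for that pair.  Windows with no comparable site are
    ``nan``.
    """

    window: int
    step: int
    window_start: np.ndarray  # 1-based
    window_mid: np.ndarray
    pi: np.ndarray
    overall_pi: float


def sliding_pi(
    rows: Iterable[str] | CodonAlignment, window: int = 200, step: int = 20
) -> DiversitySeries:
    """Sliding-window pi over an aligned nucleotide matrix."""
    if isinstance(rows, CodonAlignment):
        rows = rows.rows
    rows = [r.upper().replace("U", "T") for r in rows]
    if len(rows) < 2:
        raise ValueError("diversity needs at least 2 aligned sequences")
    if len({len(r) for r in rows}) > 1:
        raise ValueError("alignment rows differ in length")
    length = len(rows[0])
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")

    arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), length)
    valid_base = np.isin(arr, np.array([b"A", b"C", b"G", b"T"]))

    pair_diff = []  # per pair: boolean arrays along sites
    pair_valid = []
    for i, j in combinations(range(len(rows)), 2):
        both = valid_base[i] & valid_base[j]
        pair_valid.append(both)
        pair_diff.append(both & (arr[i] != arr[j]))
    diff_cum = np.concatenate(
        [np.zeros((len(pair_diff), 1)), np.cumsum(pair_diff, axis=1)], axis=1
    )
    valid_cum = np.concatenate(
        [np.zeros((len(pair_valid), 1)), np.cumsum(pair_valid, axis=1)], axis=1
    )

    def mean_pi(lo: int, hi: int) -> float:  # 0-based half-open site range
        d = diff_cum[:, hi] - diff_cum[:, lo]
        v = valid_cum[:, hi] - valid_cum[:, lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = d / v
        ratios = ratios[v > 0]
        return float(ratios.mean()) if ratios.size else math.nan

    starts = np.arange(1, length - window + 2, step, dtype=int)
    pis = np.array([mean_pi(s - 1, s - 1 + window) for s in starts])
    mids = starts + (window - 1) / 2.0
    return DiversitySeries(
        window=window,
        step=step,
        window_start=starts,
        window_mid=mids,
        pi=pis,
        overall_pi=mean_pi(0, length),
    )
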