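"""Codon counting and codon-usage-bias diagnostics.

Implements the classical descriptive toolkit for codon-usage analysis of
mitochondrial protein-coding genes:

* relative synonymous codon usage (RSCU): observed count of a codon times
  its family size over the family total; 1 means no bias;
* Wright's effective number of codons (ENc), on a 20-61 nominal scale where
  lower means stronger bias, with the mutation-drift expectation
  ``ENc_exp = 2 + GC3s + 29 / (GC3s^2 + (1 - GC3s)^2)`` used for ENc plots;
* parity-rule-2 (PR2) coordinates ``x = G3/(G3+C3)``, ``y = A3/(A3+T3)``,
  where (0.5, 0.5) is the mutation-selection equilibrium point;
* the neutrality regression of GC12 on GC3.

Synonymous families follow the convention of splitting six-fold amino acids
into sub-families sharing their first two codon bases (Leu1 = CUN,
Leu2 = UUR, Ser1 = AGN, Ser2 = UCN under the invertebrate mitochondrial
code, NCBI table 5), which leaves every sense codon in a two- or four-fold
family under that code.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np
from scipy import stats

__all__ = [
    "GeneticCode",
    "CodonUsageTable",
    "count_codons",
    "rscu",
    "aa_frequencies",
    "third_position_composition",
    "enc",
    "enc_expected",
    "pr2_point",
    "neutrality_fit",
    "NeutralityFit",
    "ThirdPositionComposition",
]

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table plus the synonymous-family partition.

    Families group codons with the same amino acid *and* the same first two
    bases, which reproduces the Leu1/Leu2 and Ser1/Ser2 split convention and
    makes every family two- or four-fold under the invertebrate
    mitochondrial code.
    """

    table_id: int
    codon_to_aa: dict[str, str]  # sense codons only
    stop_codons: frozenset[str]
    families: dict[str, tuple[str, ...]]  # family label -> codons
    codon_to_family: dict[str, str]

    @classmethod
    def from_ncbi(cls, table_id: int = 5) -> "GeneticCode":
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[table_id]
        codon_to_aa = dict(table.forward_table)
        stops = frozenset(table.stop_codons)

        groups: dict[tuple[str, str], list[str]] = {}
        for codon, aa in codon_to_aa.items():
            groups.setdefault((aa, codon[:2]), []).append(codon)
        # number sub-families of split amino acids by prefix order
        # (CUN < UUR gives Leu1/Leu2; AGN < UCN gives Ser1/Ser2)
        by_aa: dict[str, list[str]] = {}
        for aa, prefix in sorted(groups):
            by_aa.setdefault(aa, []).append(prefix)
        families: dict[str, tuple[str, ...]] = {}
        codon_to_family: dict[str, str] = {}
        for aa, prefixes in by_aa.items():
            for i, prefix in enumerate(prefixes):
                label = _AA3[aa] if len(prefixes) == 1 else f"{_AA3[aa]}{i + 1}"
                codons = tuple(sorted(groups[(aa, prefix)]))
                families[label] = codons
                for c in codons:
                    codon_to_family[c] = label
        return cls(
            table_id=table_id,
            codon_to_aa=codon_to_aa,
            stop_codons=stops,
            families=families,
            codon_to_family=codon_to_family,
        )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.codon_to_aa))

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


INVERTEBRATE_MITO = GeneticCode.from_ncbi(5)


def count_codons(
    cds: str,
    code: GeneticCode = INVERTEBRATE_MITO,
    drop_incomplete_stop: bool = True,
) -> Counter:
    """Count codons of an in-frame CDS (frame 0).

    A trailing 1-2 nt remainder is treated as an incomplete stop codon
    (completed by polyadenylation in mitochondrial transcripts) and dropped
    when ``drop_incomplete_stop`` is set.  Stop codons are counted in the
    returned mapping but excluded from all downstream usage statistics.
    Internal stop codons trigger a warning naming the codon position, since
    they usually indicate a frame error.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    remainder = len(cds) % 3
    if remainder and not drop_incomplete_stop:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if remainder:
        cds = cds[: len(cds) - remainder]
    counts: Counter = Counter()
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        counts[codon] += 1
        if code.is_stop(codon) and i < n_codons - 1:
            warnings.warn(
                f"internal stop codon {codon} at codon {i + 1}; possible frame error"
            )
    return counts


def _sense_counts(codon_counts: dict, code: GeneticCode) -> dict[str, int]:
    return {
        c: n
        for c, n in codon_counts.items()
        if c in code.codon_to_aa and n > 0
    }


def rscu(codon_counts: dict, code: GeneticCode = INVERTEBRATE_MITO) -> dict[str, float]:
    """RSCU for every sense codon.

    ``RSCU(c) = count(c) * family_size / family_total``.  Codons of a family
    with zero total usage get ``nan`` (undefined, flagged by a warning);
    unused codons in a used family get 0.
    """
    out: dict[str, float] = {}
    for label, codons in code.families.items():
        total = sum(codon_counts.get(c, 0) for c in codons)
        if total == 0:
            for c in codons:
                out[c] = math.nan
            continue
        k = len(codons)
        for c in codons:
            out[c] = codon_counts.get(c, 0) * k / total
    if any(math.isnan(v) for v in out.values()):
        warnings.warn("one or more synonymous families unused; their RSCU is undefined")
    return out


def aa_frequencies(codon_counts: dict, code: GeneticCode = INVERTEBRATE_MITO) -> dict[str, float]:
    """Percent usage of each synonymous family among all sense codons."""
    totals = {
        label: sum(codon_counts.get(c, 0) for c in codons)
        for label, codons in code.families.items()
    }
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("no sense codons counted")
    return {label: 100.0 * n / grand for label, n in totals.items()}


class ThirdPositionComposition(NamedTuple):
    a3: float  # percent of third positions, sense codons only
    t3: float
    g3: float
    c3: float
    gc3: float
    gc3s: float
    gc12: float


def third_position_composition(
    codon_counts: dict, code: GeneticCode = INVERTEBRATE_MITO
) -> ThirdPositionComposition:
    """Positional base content of a codon-count table (percent).

    ``gc3`` is over all sense codons; ``gc3s`` restricts to codons whose
    family has size >= 2 (under the split convention of the invertebrate
    mitochondrial code that is every sense codon, so gc3 == gc3s there);
    ``gc12`` is the mean GC percent of codon positions 1 and 2.
    """
    counts = _sense_counts(codon_counts, code)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no sense codons counted")
    pos_base = [Counter(), Counter(), Counter()]
    syn_gc3 = 0
    syn_total = 0
    for codon, n in counts.items():
        for i, base in enumerate(codon):
            pos_base[i][base] += n
        if len(code.families[code.codon_to_family[codon]]) >= 2:
            syn_total += n
            if codon[2] in "GC":
                syn_gc3 += n
    third = pos_base[2]
    pct = lambda x: 100.0 * x / total
    gc1 = pct(pos_base[0]["G"] + pos_base[0]["C"])
    gc2 = pct(pos_base[1]["G"] + pos_base[1]["C"])
    return ThirdPositionComposition(
        a3=pct(third["A"]),
        t3=pct(third["T"]),
        g3=pct(third["G"]),
        c3=pct(third["C"]),
        gc3=pct(third["G"] + third["C"]),
        gc3s=100.0 * syn_gc3 / syn_total if syn_total else math.nan,
        gc12=(gc1 + gc2) / 2.0,
    )


def enc(codon_counts: dict, code: GeneticCode = INVERTEBRATE_MITO) -> float:
    """Wright's effective number of codons.

    Per family with total *n* over codon proportions *p*:
    ``F = (n * sum(p^2) - 1) / (n - 1)``.  Families with n < 2 or F == 0 are
    excluded from their degeneracy-class mean; ENc is the sum over classes
    of (number of families in the class) / (class mean F).  A degeneracy
    class with no usable family is imputed at the uniform-usage expectation
    ``1/k`` with a warning.  The raw value is returned without clamping to
    the nominal 61 maximum.
    """
    by_class: dict[int, list[float]] = {}
    class_sizes: dict[int, int] = {}
    for label, codons in code.families.items():
        k = len(codons)
        class_sizes[k] = class_sizes.get(k, 0) + 1
        n = sum(codon_counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        p2 = sum((codon_counts.get(c, 0) / n) ** 2 for c in codons)
        f_hat = (n * p2 - 1) / (n - 1)
        if f_hat == 0:
            continue
        by_class.setdefault(k, []).append(f_hat)
    value = 0.0
    for k, n_families in sorted(class_sizes.items()):
        fs = by_class.get(k)
        if not fs:
            warnings.warn(
                f"no usable family of degeneracy {k}; imputing F = 1/{k}"
            )
            f_bar = 1.0 / k
        else:
            f_bar = sum(fs) / len(fs)
        value += n_families / f_bar
    if value > 61:
        warnings.warn(f"ENc estimate {value:.2f} exceeds the nominal maximum 61")
    return value


def enc_expected(gc3s: float) -> float:
    """Mutation-drift ENc expectation at a given GC3s (fraction in [0, 1])."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError("gc3s must be a fraction in [0, 1]")
    return 2.0 + gc3s + 29.0 / (gc3s**2 + (1.0 - gc3s) ** 2)


def pr2_point(
    codon_counts: dict, code: GeneticCode = INVERTEBRATE_MITO
) -> tuple[float, float]:
    """PR2-bias coordinates ``(G3/(G3+C3), A3/(A3+T3))`` of a gene.

    Genes with no G *and* no C at third positions have an undefined
    abscissa, returned as ``nan`` with a warning (likewise for the
    ordinate); a gene lacking only G gets x = 0 exactly.
    """
    comp = third_position_composition(codon_counts, code)
    if comp.g3 + comp.c3 == 0:
        warnings.warn("no G or C at third codon positions; PR2 abscissa undefined")
        x = math.nan
    else:
        x = comp.g3 / (comp.g3 + comp.c3)
    if comp.a3 + comp.t3 == 0:
        warnings.warn("no A or T at third codon positions; PR2 ordinate undefined")
        y = math.nan
    else:
        y = comp.a3 / (comp.a3 + comp.t3)
    return x, y


class NeutralityFit(NamedTuple):
    slope: float
    intercept: float
    r2: float
    p_value: float


def neutrality_fit(points: Iterable[tuple[float, float]]) -> NeutralityFit:
    """OLS regression of GC12 on GC3 over (gc3, gc12) points.

    The p-value is the two-sided t-test of slope != 0 on n - 2 degrees of
    freedom.  Zero variance in GC3 leaves the slope undefined (nan, with a
    warning).
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("neutrality regression needs at least 3 points")
    x = np.asarray([p[0] for p in pts], dtype=float)
    y = np.asarray([p[1] for p in pts], dtype=float)
    if np.ptp(x) == 0:
        warnings.warn("zero variance in GC3; neutrality slope undefined")
        return NeutralityFit(math.nan, math.nan, math.nan, math.nan)
    if np.ptp(y) == 0:  # flat response: slope 0, no explained variance
        return NeutralityFit(0.0, float(y[0]), 0.0, 1.0)
    res = stats.linregress(x, y)
    return NeutralityFit(res.slope, res.intercept, res.rvalue**2, res.pvalue)


@dataclass
class CodonUsageTable:
    """All codon-usage statistics of one gene (or concatenated gene set)."""

    gene: str
    codon_counts: Counter
    rscu: dict[str, float]
    aa_freq: dict[str, float]
    third: ThirdPositionComposition
    enc: float
    pr2_x: float
    pr2_y: float
    code: GeneticCode = field(repr=False, default=INVERTEBRATE_MITO)

    @classmethod
    def from_cds(
        cls, gene: str, cds: str, code: GeneticCode = INVERTEBRATE_MITO
    ) -> "CodonUsageTable":
        counts = count_codons(cds, code)
        x, y = pr2_point(counts, code)
        return cls(
            gene=gene,
            codon_counts=counts,
            rscu=rscu(counts, code),
            aa_freq=aa_frequencies(counts, code),
            third=third_position_composition(counts, code),
            enc=enc(counts, code),
            pr2_x=x,
            pr2_y=y,
            code=code,
        )

    @property
    def n_codons_used(self) -> int:
        """Number of distinct sense codons with count > 0."""
        return len(_sense_counts(self.codon_counts, self.code))
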