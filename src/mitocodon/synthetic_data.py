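"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate the data classes the analysis modules consume: high-AT
circular mitogenomes with a planted feature organization, coding sequences
drawn from a specified codon-frequency profile, and sets of coding sequences
diverged under a codon substitution process with a chosen dN/dS (omega).
Every generator is a pure function of its spec: the same seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codon_usage import INVERTEBRATE_MITO, GeneticCode
from .divergence import CodonAlignment
from .genome_model import (
    AnnotatedGenome,
    Feature,
    FeatureKind,
    Strand,
    reverse_complement,
)
from .repeats import _complement  # complement without reversal

__all__ = [
    "GenomeSpec",
    "DivergenceSpec",
    "EvolvedSet",
    "make_genome",
    "make_codon_set",
    "evolve_pair",
    "reference_feature_plan",
]

#: (name, kind, strand, length bp, gap to next feature; negative = overlap)
FeaturePlan = Sequence[tuple[str, str, str, int, int]]

#: (kind, sequence, positions): kind "segment" writes the sequence at one
#: position; the dispersed kinds write the sequence at positions[0] and its
#: class transform at positions[1].
PlantedRepeat = tuple[str, str, tuple[int, ...]]


@dataclass
class GenomeSpec:
    genome_length: int
    at_target: float
    feature_plan: FeaturePlan
    planted_repeats: list[PlantedRepeat] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.at_target < 1:
            raise ValueError("at_target must be in (0, 1)")
        total = sum(length + gap for _, _, _, length, gap in self.feature_plan)
        if self.feature_plan and total != self.genome_length:
            raise ValueError(
                f"feature plan does not tile the circle: lengths+gaps={total}, "
                f"genome_length={self.genome_length}"
            )
        for name, _, _, length, gap in self.feature_plan:
            if gap < 0 and -gap >= length:
                raise ValueError(f"{name}: overlap {-gap} exceeds feature length")


def _background(length: int, at: float, rng: np.random.Generator) -> np.ndarray:
    """Random sequence with *exact* base counts at the AT target (even A/T
    and G/C split), so composition matches the target up to rounding."""
    n_at = round(length * at)
    n_a = n_at - n_at // 2
    n_g = (length - n_at) // 2
    arr = np.array(
        ["A"] * n_a + ["T"] * (n_at - n_a) + ["G"] * n_g + ["C"] * (length - n_at - n_g),
        dtype="U1",
    )
    rng.shuffle(arr)
    return arr


def _write(seq: np.ndarray, pos: int, fragment: str, genome_length: int) -> None:
    for i, base in enumerate(fragment):
        seq[(pos - 1 + i) % genome_length] = base


def make_genome(spec: GenomeSpec, code: GeneticCode = INVERTEBRATE_MITO) -> AnnotatedGenome:
    """Build an annotated circular genome with sequence from a spec.

    Features are laid head-to-tail from position 1 following the plan's
    lengths and gaps (negative gaps create overlaps).  The background is an
    exact-count shuffle at the AT target; protein-coding features then get a
    valid ATN start codon and a TAA/TA/T stop matching their length modulo
    3, and planted repeats are written last (so their ground truth is exact,
    even inside features).
    """
    rng = np.random.default_rng(spec.seed)
    seq = _background(spec.genome_length, spec.at_target, rng)

    features: list[Feature] = []
    cursor = 1
    for name, kind, strand, length, gap in spec.feature_plan:
        # modular placement: a feature crossing the origin wraps (end < start)
        start = (cursor - 1) % spec.genome_length + 1
        end = (start + length - 2) % spec.genome_length + 1
        start_codon: Optional[str] = None
        stop_codon: Optional[str] = None
        if kind == "PCG":
            start_codon = str(rng.choice(["ATG", "ATA", "ATT"]))
            stop_codon = {0: "TAA", 1: "T", 2: "TA"}[length % 3]
            if strand == "+":
                _write(seq, start, start_codon, spec.genome_length)
                _write(seq, end - len(stop_codon) + 1, stop_codon, spec.genome_length)
            else:
                _write(seq, end - 2, reverse_complement(start_codon), spec.genome_length)
                _write(seq, start, reverse_complement(stop_codon), spec.genome_length)
        features.append(
            Feature(
                name=name,
                kind=FeatureKind(kind),
                strand=Strand(strand),
                start=start,
                end=end,
                start_codon=start_codon,
                stop_codon=stop_codon,
            )
        )
        cursor = cursor + length + gap

    for kind, fragment, positions in spec.planted_repeats:
        fragment = fragment.upper()
        if kind == "segment":
            _write(seq, positions[0], fragment, spec.genome_length)
        elif kind in ("forward", "reverse", "palindromic", "complementary"):
            transform = {
                "forward": lambda s: s,
                "reverse": lambda s: s[::-1],
                "palindromic": reverse_complement,
                "complementary": _complement,
            }[kind]
            _write(seq, positions[0], fragment, spec.genome_length)
            _write(seq, positions[1], transform(fragment), spec.genome_length)
        else:
            raise ValueError(f"unknown planted repeat kind {kind!r}")

    return AnnotatedGenome(
        genome_length=spec.genome_length,
        features=features,
        sequence="".join(seq),
        topology="circular",
    )


def reference_feature_plan() -> tuple[int, FeaturePlan]:
    """(genome_length, plan) replaying the bundled aphid annotation.

    Lengths and inter-feature gaps are taken from the bundled feature table,
    so a genome built from this plan reproduces the published organization
    arithmetic exactly.
    """
    from .genome_model import load_reference_annotation

    genome = load_reference_annotation()
    feats = genome.features
    plan = []
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        if i + 1 < len(feats):
            gap = nxt.start - f.end - 1
        else:
            gap = genome.genome_length - f.end - 1 + nxt.start
        plan.append((f.name, f.kind.value, f.strand.value, f.length(genome.genome_length), gap))
    return genome.genome_length, plan


def make_codon_set(
    profile: dict[str, float],
    n_codons: int,
    seed: int,
    code: GeneticCode = INVERTEBRATE_MITO,
    stop: str = "TAA",
) -> str:
    """CDS string of ``n_codons`` sense codons drawn from a profile + a stop.

    The profile must put its mass on sense codons only and sum to 1.
    """
    codons = sorted(profile)
    for c in codons:
        if code.is_stop(c):
            raise ValueError(f"profile puts mass on stop codon {c}")
        if c not in code.codon_to_aa:
            raise ValueError(f"unknown codon {c}")
    probs = np.array([profile[c] for c in codons], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("profile must sum to 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(codons), size=n_codons, p=probs)
    return "".join(codons[i] for i in draws) + stop


# ---------------------------------------------------------------------------
# Codon-model divergence simulation

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class DivergenceSpec:
    n_codons: int
    omega: float
    branch_length: float  # expected substitutions per codon site, per lineage
    kappa: float = 2.0  # transition/transversion rate ratio
    n_taxa: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1 or self.n_taxa < 2:
            raise ValueError("n_codons >= 1 and n_taxa >= 2 required")
        if self.omega < 0 or self.kappa <= 0 or self.branch_length < 0:
            raise ValueError("omega >= 0, kappa > 0, branch_length >= 0 required")


@dataclass
class EvolvedSet:
    alignment: CodonAlignment
    ancestor: str
    n_syn_events: list[int]  # per taxon
    n_nonsyn_events: list[int]
    spec: DivergenceSpec


def _codon_moves(code: GeneticCode, kappa: float):
    """Per sense codon: list of (target codon, base rate, is_synonymous)."""
    moves: dict[str, list[tuple[str, float, bool]]] = {}
    for codon, aa in code.codon_to_aa.items():
        lst = []
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                target = codon[:pos] + b + codon[pos + 1 :]
                if code.is_stop(target):
                    continue
                rate = kappa if _TRANSITION[codon[pos]] == b else 1.0
                lst.append((target, rate, code.codon_to_aa[target] == aa))
        moves[codon] = lst
    return moves


def evolve_pair(
    spec: DivergenceSpec, code: GeneticCode = INVERTEBRATE_MITO, gene: str = "sim"
) -> EvolvedSet:
    """Gillespie simulation of a codon substitution process on a star tree.

    Each lineage evolves independently from a common random ancestor
    (uniform sense-codon frequencies) for ``branch_length`` expected
    substitutions per codon site; omega multiplies every nonsynonymous rate
    and rates are normalised so that the neutral (omega = 1) process has
    unit expected substitutions per codon per unit time.  True synonymous
    and nonsynonymous event counts are recorded per lineage.
    """
    rng = np.random.default_rng(spec.seed)
    sense = list(code.sense_codons)
    moves = _codon_moves(code, spec.kappa)
    # normalisation: mean total neutral rate over uniform sense codons
    z = np.mean([sum(rate for _, rate, _ in moves[c]) for c in sense])

    ancestor_idx = rng.integers(0, len(sense), size=spec.n_codons)
    ancestor = [sense[i] for i in ancestor_idx]

    rows: list[str] = []
    syn_events: list[int] = []
    nonsyn_events: list[int] = []
    for _ in range(spec.n_taxa):
        n_syn = n_nonsyn = 0
        evolved = []
        for codon in ancestor:
            state = codon
            t = 0.0
            while True:
                options = moves[state]
                rates = np.array(
                    [r * (1.0 if is_syn else spec.omega) for _, r, is_syn in options]
                ) / z
                total = rates.sum()
                if total == 0:
                    break
                t += rng.exponential(1.0 / total)
                if t > spec.branch_length:
                    break
                pick = rng.choice(len(options), p=rates / total)
                target, _, is_syn = options[pick]
                if is_syn:
                    n_syn += 1
                else:
                    n_nonsyn += 1
                state = target
            evolved.append(state)
        rows.append("".join(evolved))
        syn_events.append(n_syn)
        nonsyn_events.append(n_nonsyn)

    taxa = [f"taxon{i + 1}" for i in range(spec.n_taxa)]
    return EvolvedSet(
        alignment=CodonAlignment(gene=gene, taxa=taxa, rows=rows),
        ancestor="".join(ancestor),
        n_syn_events=syn_events,
        n_nonsyn_events=nonsyn_events,
        spec=spec,
    )
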