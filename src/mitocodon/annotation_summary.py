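"""Gene-organization arithmetic: sizes, intergenic spacers, overlaps, strands.

The adjacency convention is the one used in printed mitogenome annotation
tables: for consecutive features *i*, *i+1* (sorted by start coordinate),

    gap = start(i+1) - end(i) - 1

A positive gap is an intergenic spacer of that many bases, a negative gap an
overlap of ``|gap|`` bases, and zero means the features abut and count in
neither class.  On a circular genome the pair (last feature, first feature)
is evaluated across the origin.  Non-coding regions participate in adjacency
exactly like genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .genome_model import AnnotatedGenome, Feature, FeatureKind, Strand

__all__ = [
    "OrganizationReport",
    "feature_lengths",
    "intergenic_profile",
    "strand_partition",
    "pcg_size_summary",
]


@dataclass
class OrganizationReport:
    """Summary of the gene organization of one annotated genome."""

    #: (name, kind, strand, length bp, gap to previous feature or None)
    per_feature: list[tuple[str, FeatureKind, Strand, int, Optional[int]]]
    n_overlaps: int
    n_spacers: int
    overlap_range: Optional[tuple[int, int]]  # (min bp, max bp) of |gap|
    spacer_range: Optional[tuple[int, int]]
    counts: dict[FeatureKind, int]
    strand_counts: dict[tuple[FeatureKind, Strand], int] = field(default_factory=dict)

    @property
    def gaps(self) -> list[Optional[int]]:
        return [row[4] for row in self.per_feature]


def feature_lengths(genome: AnnotatedGenome) -> dict[str, int]:
    """Length in bp of every feature (wrapping-aware), keyed by name."""
    if not genome.features:
        raise ValueError("genome has no features")
    return {f.name: f.length(genome.genome_length) for f in genome.features}


def _adjacent_gaps(genome: AnnotatedGenome) -> list[Optional[int]]:
    """Gap to the *previous* feature, aligned with the sorted feature list.

    The first feature's entry is the across-the-origin gap on circular
    genomes and ``None`` on linear ones.
    """
    feats = genome.features
    starts = [f.start for f in feats]
    if starts != sorted(starts):
        raise ValueError("features must be sorted by start coordinate")
    gaps: list[Optional[int]] = []
    for i, f in enumerate(feats):
        if i == 0:
            if genome.topology == "circular" and len(feats) > 1:
                prev = feats[-1]
                if prev.wraps:  # its end already lies past the origin
                    gaps.append(f.start - prev.end - 1)
                else:
                    gaps.append(genome.genome_length - prev.end - 1 + f.start)
            else:
                gaps.append(None)
        else:
            gaps.append(f.start - feats[i - 1].end - 1)
    return gaps


def intergenic_profile(genome: AnnotatedGenome) -> OrganizationReport:
    """Spacer/overlap profile over all adjacent feature pairs."""
    feats = genome.features
    gaps = _adjacent_gaps(genome)
    per_feature = [
        (f.name, f.kind, f.strand, f.length(genome.genome_length), g)
        for f, g in zip(feats, gaps)
    ]
    real_gaps = [g for g in gaps if g is not None]
    spacers = [g for g in real_gaps if g > 0]
    overlaps = [-g for g in real_gaps if g < 0]
    counts: dict[FeatureKind, int] = {}
    strand_counts: dict[tuple[FeatureKind, Strand], int] = {}
    for f in feats:
        counts[f.kind] = counts.get(f.kind, 0) + 1
        key = (f.kind, f.strand)
        strand_counts[key] = strand_counts.get(key, 0) + 1
    return OrganizationReport(
        per_feature=per_feature,
        n_overlaps=len(overlaps),
        n_spacers=len(spacers),
        overlap_range=(min(overlaps), max(overlaps)) if overlaps else None,
        spacer_range=(min(spacers), max(spacers)) if spacers else None,
        counts=counts,
        strand_counts=strand_counts,
    )


def strand_partition(
    genome: AnnotatedGenome,
) -> dict[tuple[FeatureKind, Strand], list[str]]:
    """Feature names grouped by (kind, strand); every feature appears once."""
    out: dict[tuple[FeatureKind, Strand], list[str]] = {}
    for f in genome.features:
        out.setdefault((f.kind, f.strand), []).append(f.name)
    return out


def pcg_size_summary(genome: AnnotatedGenome) -> dict[str, int]:
    """Total protein-coding length, raw and with annotated stops excluded.

    Returns ``raw_bp`` (sum of annotated PCG sizes), ``coding_bp`` (raw minus
    the annotated stop-codon lengths, including single-T incomplete stops)
    and ``amino_acids`` (``coding_bp // 3``).  Both totals are reported
    because a printed per-gene size column and a printed grand total can
    disagree by a few stop-codon bases; no guess is made about which is
    authoritative.
    """
    raw = 0
    stops = 0
    for f in genome.by_kind(FeatureKind.PCG):
        raw += f.length(genome.genome_length)
        stops += len(f.stop_codon) if f.stop_codon else 0
    coding = raw - stops
    return {"raw_bp": raw, "coding_bp": coding, "amino_acids": coding // 3}
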