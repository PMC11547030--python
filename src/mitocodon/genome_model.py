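"""Data model and I/O for annotated circular mitochondrial genomes.

This module is the single source of coordinate conventions for the whole
package: positions are 1-based and inclusive on both ends, matching the way
mitogenome annotation tables are printed.  A feature whose ``end`` is smaller
than its ``start`` wraps across the origin of a circular molecule.

Supported inputs are GenBank flat files (the deposit format of mitogenome
accessions) and a plain feature-table TSV with columns
``Gene/Strand/Start/End/Kind[/StartCodon/StopCodon/Anticodon]`` so that a
transcribed annotation table can drive every downstream analysis without the
sequence itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "FeatureKind",
    "Strand",
    "Feature",
    "AnnotatedGenome",
    "reverse_complement",
    "read_genbank",
    "read_feature_tsv",
    "write_feature_tsv",
    "extract_cds",
    "load_reference_annotation",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Canonical column order of the feature-table TSV (round-trip stable).
TSV_COLUMNS = [
    "Gene",
    "Strand",
    "Start",
    "End",
    "Kind",
    "StartCodon",
    "StopCodon",
    "Anticodon",
]


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FeatureKind(str, Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    NONCODING = "noncoding"


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"


@dataclass(frozen=True)
class Feature:
    """One annotated element: gene, RNA, or non-coding region.

    ``start``/``end`` are 1-based inclusive.  ``end < start`` denotes a
    feature wrapping the circular origin.  Length is always derived, never
    stored.
    """

    name: str
    kind: FeatureKind
    strand: Strand
    start: int
    end: int
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    anticodon: Optional[str] = None

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """Ordered feature table plus (optionally) the genome sequence."""

    genome_length: int
    features: list[Feature] = field(default_factory=list)
    sequence: Optional[str] = None
    topology: str = "circular"  # or "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.sequence is not None and len(self.sequence) != self.genome_length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != genome_length "
                f"{self.genome_length}"
            )
        seen: set[tuple[str, Strand]] = set()
        for f in self.features:
            for coord in (f.start, f.end):
                if not 1 <= coord <= self.genome_length:
                    raise ValueError(
                        f"feature {f.name}: coordinate {coord} outside "
                        f"[1, {self.genome_length}]"
                    )
            if f.wraps and self.topology != "circular":
                raise ValueError(f"feature {f.name} wraps a linear genome")
            key = (f.name, f.strand)
            if key in seen:
                raise ValueError(f"duplicate feature {f.name} on strand {f.strand.value}")
            seen.add(key)
        self.features = sorted(self.features, key=lambda f: f.start)

    def get(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_kind(self, kind: FeatureKind) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


# ---------------------------------------------------------------------------
# GenBank input

_GENBANK_KIND = {
    "CDS": FeatureKind.PCG,
    "tRNA": FeatureKind.TRNA,
    "rRNA": FeatureKind.RRNA,
    "misc_feature": FeatureKind.NONCODING,
    "D-loop": FeatureKind.NONCODING,
    "rep_origin": FeatureKind.NONCODING,
}


def _feature_name(qualifiers: dict) -> Optional[str]:
    for key in ("gene", "product", "note", "standard_name"):
        if key in qualifiers and qualifiers[key]:
            return str(qualifiers[key][0])
    return None


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Read a GenBank flat file into an :class:`AnnotatedGenome`.

    CDS/tRNA/rRNA/misc_feature entries become features with 1-based inclusive
    coordinates; ``complement()`` locations are flagged minus-strand and
    ``join()`` locations spanning the origin become wrapping features.  A
    record without an ORIGIN section yields ``sequence=None`` with a warning.
    """
    from Bio import SeqIO
    from Bio.Seq import UndefinedSequenceError

    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:  # malformed locations surface here
        raise ValueError(f"cannot parse GenBank file {path}: {exc}") from exc

    try:
        sequence: Optional[str] = str(record.seq).upper()
    except UndefinedSequenceError:
        warnings.warn(f"{path}: no ORIGIN sequence; proceeding without sequence")
        sequence = None

    length = len(record.seq)
    topology = record.annotations.get("topology", "circular")
    if topology not in ("circular", "linear"):
        topology = "circular"

    features: list[Feature] = []
    for feat in record.features:
        kind = _GENBANK_KIND.get(feat.type)
        if kind is None:
            continue
        name = _feature_name(feat.qualifiers)
        if name is None:
            raise ValueError(f"GenBank feature of type {feat.type} at {feat.location} has no name")
        loc = feat.location
        parts = getattr(loc, "parts", [loc])
        # join() across the origin: first part carries the start, last the end
        start = int(parts[0].start) + 1
        end = int(parts[-1].end)
        strand = Strand.MINUS if loc.strand == -1 else Strand.PLUS
        features.append(Feature(name=name, kind=kind, strand=strand, start=start, end=end))
    return AnnotatedGenome(
        genome_length=length, features=features, sequence=sequence, topology=topology
    )


# ---------------------------------------------------------------------------
# Feature-table TSV input/output


def read_feature_tsv(
    path: str | Path, genome_length: int, topology: str = "circular"
) -> AnnotatedGenome:
    """Read a ``Gene/Strand/Start/End/Kind[...]`` TSV into a genome model.

    The resulting model is identical to what :func:`read_genbank` builds,
    except the sequence is absent.  Coordinates outside
    ``[1, genome_length]`` raise a validation error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"Gene", "Strand", "Start", "End", "Kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    features = []
    for row in df.itertuples(index=False):
        features.append(
            Feature(
                name=row.Gene,
                kind=FeatureKind(row.Kind),
                strand=Strand(row.Strand),
                start=int(row.Start),
                end=int(row.End),
                start_codon=getattr(row, "StartCodon", "") or None,
                stop_codon=getattr(row, "StopCodon", "") or None,
                anticodon=getattr(row, "Anticodon", "") or None,
            )
        )
    return AnnotatedGenome(
        genome_length=genome_length, features=features, sequence=None, topology=topology
    )


def write_feature_tsv(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write the feature table in canonical column order (round-trip safe)."""
    rows = [
        {
            "Gene": f.name,
            "Strand": f.strand.value,
            "Start": f.start,
            "End": f.end,
            "Kind": f.kind.value,
            "StartCodon": f.start_codon or "",
            "StopCodon": f.stop_codon or "",
            "Anticodon": f.anticodon or "",
        }
        for f in genome.features
    ]
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sequence access


def extract_region(genome: AnnotatedGenome, start: int, end: int) -> str:
    """Forward-strand slice, 1-based inclusive, wrapping-aware."""
    if genome.sequence is None:
        raise ValueError("genome has no sequence; cannot extract regions")
    if end >= start:
        return genome.sequence[start - 1 : end]
    if genome.topology != "circular":
        raise ValueError("wrapping slice requested on a linear genome")
    return genome.sequence[start - 1 :] + genome.sequence[:end]


def extract_cds(genome: AnnotatedGenome, feature: Feature) -> str:
    """Annotated-strand sequence of a feature.

    Minus-strand features are reverse complemented; wrapping features
    concatenate the tail and head of the circle.  Incomplete stop codons are
    preserved exactly as annotated (the returned length equals the feature
    length, which may not be a multiple of three).
    """
    segment = extract_region(genome, feature.start, feature.end)
    if feature.strand is Strand.MINUS:
        segment = reverse_complement(segment)
    return segment


# ---------------------------------------------------------------------------
# Bundled reference annotation (transcribed aphid mitogenome feature table)

REFERENCE_GENOME_LENGTH = 15772


def load_reference_annotation() -> AnnotatedGenome:
    """The bundled 15,772 bp waterlily-aphid mitogenome feature table.

    40 features: 13 protein-coding genes, 22 tRNAs, 2 rRNAs and the two
    non-coding regions (control region CR, aphid repeat region RR).  The
    sequence itself is not bundled; all arithmetic on this annotation is
    coordinate-based.
    """
    from importlib.resources import files

    path = files("mitocodon.data").joinpath("aphid_mitogenome_features.tsv")
    return read_feature_tsv(str(path), REFERENCE_GENOME_LENGTH)
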