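"""Circular mitochondrial reference genome: sequence, features, codons, regions.

The reference strand is the light (L) strand, i.e. the strand reported by the
variant caller.  All external coordinates are 1-based inclusive (VCF
convention), and position arithmetic wraps modulo the genome length because
animal mtDNA is circular: a feature may have ``start > end``, in which case it
spans the origin.

Coding-sequence lookups use the vertebrate mitochondrial genetic code (NCBI
translation table 2: TGA=Trp, ATA=Met, AGA/AGG=stop) and a five-class amino
acid property scheme (hydrophobic / hydrophilic / acidic / basic / stop).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable as _bio_codon_table

logger = logging.getLogger(__name__)

#: The four annotated region classes; mutations outside all of them are
#: reported as "intergenic".
REGION_KINDS = ("CDS", "tRNA", "rRNA", "D-loop")

#: When degenerate annotations overlap, a position is assigned to the
#: highest-precedence kind (left to right).
REGION_PRECEDENCE = {kind: rank for rank, kind in enumerate(REGION_KINDS)}

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Amino-acid property classes.  The scheme groups residues by side-chain
#: chemistry; glycine is grouped with the hydrophobic residues and cysteine
#: with the hydrophilic ones.  Overridable wherever a property lookup is taken.
DEFAULT_PROPERTY_MAP: Mapping[str, str] = {
    **{aa: "hydrophobic" for aa in "AVLIPFMWG"},
    **{aa: "hydrophilic" for aa in "STCYNQ"},
    **{aa: "acidic" for aa in "DE"},
    **{aa: "basic" for aa in "KRH"},
    "*": "stop",
}


class AnnotationError(ValueError):
    """Malformed or out-of-bounds feature annotation."""


class IncompleteCodonError(ValueError):
    """Position falls in an incomplete terminal codon (genes completed by
    polyadenylation in vivo); such positions are excluded from codon-effect
    annotation."""


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class Feature:
    """A typed, stranded annotation interval on the circular genome.

    ``start``/``end`` are 1-based inclusive on the reference (L) strand;
    ``start > end`` means the feature wraps the origin.  ``strand`` is '+'
    when the coding strand is the reference strand.  For CDS features,
    ``reading_frame_origin`` is the reference coordinate of the *first coding
    base* (defaults to ``start`` on '+', ``end`` on '-').
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    reading_frame_origin: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise AnnotationError(
                f"feature {self.name!r}: unknown kind {self.kind!r} "
                f"(expected one of {REGION_KINDS})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"feature {self.name!r}: bad strand {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise AnnotationError(f"feature {self.name!r}: coordinates must be >= 1")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int) -> int:
        if not self.wraps:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end

    def contains(self, pos: int) -> bool:
        if not self.wraps:
            return self.start <= pos <= self.end
        return pos >= self.start or pos <= self.end

    def positions(self, genome_length: int) -> Iterator[int]:
        """Reference positions in 5'→3' order along the *reference* strand."""
        for off in range(self.length(genome_length)):
            yield (self.start - 1 + off) % genome_length + 1

    def frame_origin(self) -> int:
        if self.reading_frame_origin is not None:
            return self.reading_frame_origin
        return self.start if self.strand == "+" else self.end


@dataclass
class CodonTable:
    """64-codon → amino acid map plus an amino-acid property map."""

    forward: Mapping[str, str]
    property_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_PROPERTY_MAP))

    def __post_init__(self) -> None:
        if len(self.forward) != 64:
            raise ValueError(f"codon table has {len(self.forward)} entries, expected 64")

    @classmethod
    def vertebrate_mitochondrial(cls) -> "CodonTable":
        bio = _bio_codon_table.unambiguous_dna_by_id[2]
        forward = dict(bio.forward_table)
        for stop in bio.stop_codons:
            forward[stop] = "*"
        return cls(forward=forward)


_DEFAULT_TABLE: CodonTable | None = None


def default_codon_table() -> CodonTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = CodonTable.vertebrate_mitochondrial()
    return _DEFAULT_TABLE


def translate(codon: str, table: CodonTable | None = None) -> str:
    """Translate one codon under the vertebrate mitochondrial code.

    Returns the single-letter amino acid, or '*' for a stop codon.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"not an unambiguous DNA codon: {codon!r}")
    table = table or default_codon_table()
    return table.forward[codon]


def aa_property(aa: str, property_map: Mapping[str, str] | None = None) -> str:
    """Property class of an amino acid (or '*' → 'stop')."""
    pmap = property_map or DEFAULT_PROPERTY_MAP
    try:
        return pmap[aa]
    except KeyError:
        raise ValueError(f"unknown amino acid code: {aa!r}") from None


@dataclass
class MtReference:
    """Single circular mtDNA contig with typed features.

    ``sequence`` is the L-strand, uppercase ACGT only.
    """

    name: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"reference contains non-ACGT characters: {sorted(bad)}")
        if not self.sequence:
            raise ValueError("empty reference sequence")
        for f in self.features:
            if f.start > self.length or f.end > self.length:
                raise AnnotationError(
                    f"feature {f.name!r} ({f.start}-{f.end}) exceeds genome "
                    f"length {self.length}"
                )
        self._region_cache: list[str] | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        self._check_pos(pos)
        return self.sequence[pos - 1]

    def _check_pos(self, pos: int) -> None:
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside genome [1, {self.length}]")

    # -- region lookups ---------------------------------------------------

    def _region_labels(self) -> list[str]:
        if self._region_cache is None:
            labels = ["intergenic"] * self.length
            # paint in reverse precedence so the highest-precedence kind wins
            for f in sorted(self.features, key=lambda f: REGION_PRECEDENCE[f.kind], reverse=True):
                for pos in f.positions(self.length):
                    if labels[pos - 1] not in ("intergenic", f.kind):
                        logger.warning(
                            "overlapping annotation at pos %d: %s over %s "
                            "(precedence CDS > tRNA > rRNA > D-loop applied)",
                            pos, f.kind, labels[pos - 1],
                        )
                    labels[pos - 1] = f.kind
            self._region_cache = labels
        return self._region_cache

    def region_of(self, pos: int) -> str:
        """Region class containing ``pos``: CDS/tRNA/rRNA/D-loop/intergenic."""
        self._check_pos(pos)
        return self._region_labels()[pos - 1]

    def region_lengths(self) -> dict[str, int]:
        """Total bp per region class, including 'intergenic'."""
        out: dict[str, int] = {k: 0 for k in (*REGION_KINDS, "intergenic")}
        for label in self._region_labels():
            out[label] += 1
        return out

    def cds_at(self, pos: int) -> Feature | None:
        """The CDS feature containing ``pos`` (first in annotation order)."""
        self._check_pos(pos)
        for f in self.features:
            if f.kind == "CDS" and f.contains(pos):
                return f
        return None

    def feature_slice(self, feature: Feature) -> str:
        """Coding-strand sequence of a feature (reverse complement for '-')."""
        ref = "".join(self.base(p) for p in feature.positions(self.length))
        return ref if feature.strand == "+" else reverse_complement(ref)


@dataclass(frozen=True)
class CodonContext:
    codon: str           # 3-mer on the coding strand
    codon_position: int  # 1..3, offset of the query position within the codon
    codon_index: int     # 0-based codon number within the gene
    feature: Feature


def codon_context(ref: MtReference, pos: int) -> CodonContext:
    """Codon containing a CDS position, read on the gene's coding strand.

    For '-'-strand genes the codon is the reverse complement of the reference
    slice and ``codon_position`` counts in coding-strand orientation.  Raises
    :class:`IncompleteCodonError` for positions in a trailing partial codon.
    """
    feature = ref.cds_at(pos)
    if feature is None:
        raise ValueError(f"position {pos} is not inside any CDS feature")
    L = ref.length
    origin = feature.frame_origin()
    if feature.strand == "+":
        offset = (pos - origin) % L
    else:
        offset = (origin - pos) % L
    n_complete = feature.length(L) // 3
    codon_index = offset // 3
    if codon_index >= n_complete:
        raise IncompleteCodonError(
            f"position {pos} lies in the incomplete terminal codon of "
            f"{feature.name!r} (gene length {feature.length(L)} bp)"
        )
    bases = []
    for k in range(3):
        off = codon_index * 3 + k
        if feature.strand == "+":
            p = (origin - 1 + off) % L + 1
            bases.append(ref.base(p))
        else:
            p = (origin - 1 - off) % L + 1
            bases.append(COMPLEMENT[ref.base(p)])
    return CodonContext(
        codon="".join(bases),
        codon_position=offset % 3 + 1,
        codon_index=codon_index,
        feature=feature,
    )


# -- annotation file readers ----------------------------------------------

_GFF_KIND_ALIASES = {
    "cds": "CDS",
    "trna": "tRNA",
    "rrna": "rRNA",
    "d-loop": "D-loop",
    "d_loop": "D-loop",
    "dloop": "D-loop",
}


def _normalise_kind(raw: str, where: str) -> str:
    kind = _GFF_KIND_ALIASES.get(raw.strip().lower())
    if kind is None:
        raise AnnotationError(
            f"{where}: unknown feature kind {raw!r} "
            f"(expected one of {REGION_KINDS})"
        )
    return kind


def _parse_gff_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_features(path: str | Path) -> list[Feature]:
    """Read features from a GFF-like (1-based inclusive) or BED-like
    (0-based half-open) file; the dialect is chosen by extension.

    BED rows need 7 columns: chrom, start, end, name, score, strand, kind.
    GFF rows use column 3 as the kind and a Name/ID/gene attribute as name.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            where = f"{path.name}:{lineno}"
            if suffix == ".bed":
                if len(cols) < 7:
                    raise AnnotationError(
                        f"{where}: BED dialect needs 7 columns "
                        "(chrom start end name score strand kind)"
                    )
                start0, end0 = int(cols[1]), int(cols[2])
                features.append(
                    Feature(
                        name=cols[3],
                        kind=_normalise_kind(cols[6], where),
                        start=start0 + 1,
                        end=end0,
                        strand=cols[5],
                    )
                )
            elif suffix in (".gff", ".gff3", ".gtf"):
                if len(cols) < 8:
                    raise AnnotationError(f"{where}: GFF dialect needs >= 8 columns")
                attrs = _parse_gff_attributes(cols[8]) if len(cols) > 8 else {}
                name = attrs.get("Name") or attrs.get("ID") or attrs.get("gene") \
                    or f"{cols[2]}_{cols[3]}"
                features.append(
                    Feature(
                        name=name,
                        kind=_normalise_kind(cols[2], where),
                        start=int(cols[3]),
                        end=int(cols[4]),
                        strand=cols[6],
                    )
                )
            else:
                raise AnnotationError(
                    f"unrecognised annotation extension {suffix!r} "
                    "(expected .bed, .gff or .gff3)"
                )
    logger.info("read %d features from %s", len(features), path)
    return features


def load_reference(fasta_path: str | Path, annotation_path: str | Path) -> MtReference:
    """Load a single-record mtDNA FASTA plus its feature annotation."""
    record = SeqIO.read(str(fasta_path), "fasta")  # raises if not exactly one record
    features = read_features(annotation_path)
    return MtReference(name=record.id, sequence=str(record.seq), features=features)


def toy_reference() -> MtReference:
    """Packaged 600-bp toy genome: two complete CDS genes (one per strand),
    a CDS with an incomplete terminal codon, a tRNA, an rRNA and a D-loop."""
    from importlib.resources import files

    data = files("mtspectrum") / "data"
    return load_reference(str(data / "toy_mt.fa"), str(data / "toy_mt.gff"))
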