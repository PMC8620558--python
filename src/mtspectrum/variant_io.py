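"""Read variant calls and per-base depth tables; write classified-mutation TSVs.

Variant input is VCF 4.2 (one mitochondrial contig, one sample per file,
Mutect2-style AF/AD sample fields).  Depth input is the three-column text
emitted by ``samtools depth`` (contig, 1-based position, depth).  Classified
mutations round-trip through a documented TSV schema.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome_model import MtReference

logger = logging.getLogger(__name__)

VAR_CLASSES = ("SNV", "insertion", "deletion")


def _var_class(ref_allele: str, alt_allele: str) -> str:
    if len(ref_allele) == 1 and len(alt_allele) == 1:
        return "SNV"
    if len(alt_allele) > len(ref_allele):
        return "insertion"
    return "deletion"


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one sample (animal × tissue).

    ``pos`` is 1-based; indels are VCF-anchored (left-aligned, shared leading
    base); ``allele_fraction`` is the heteroplasmic fraction in (0, 1].
    """

    animal_id: str
    tissue: str
    pos: int
    ref_allele: str
    alt_allele: str
    allele_fraction: float
    depth: int
    var_class: str = ""

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt ({self.ref_allele!r}) at pos {self.pos}")
        if not 0 < self.allele_fraction <= 1:
            raise ValueError(
                f"allele fraction {self.allele_fraction} outside (0, 1] at pos {self.pos}"
            )
        expected = _var_class(self.ref_allele, self.alt_allele)
        if not self.var_class:
            object.__setattr__(self, "var_class", expected)
        elif self.var_class != expected:
            raise ValueError(
                f"var_class {self.var_class!r} inconsistent with alleles "
                f"{self.ref_allele}>{self.alt_allele}"
            )

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt_allele) - len(self.ref_allele))

    @property
    def key(self) -> tuple[int, str, str]:
        """Identity tuple used for germline matching: (pos, ref, alt)."""
        return (self.pos, self.ref_allele, self.alt_allele)


@dataclass
class DepthProfile:
    """Per-position sequencing depth for one sample.

    ``depth`` is indexed by position-1; ``nucleotide_depth_totals`` sums depth
    over reference positions of each base and drives the strand-asymmetry
    nucleotide-bias correction.
    """

    animal_id: str
    tissue: str
    depth: np.ndarray
    nucleotide_depth_totals: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_array(cls, animal_id: str, tissue: str, depth: np.ndarray,
                   ref: MtReference) -> "DepthProfile":
        depth = np.asarray(depth, dtype=float)
        if depth.shape != (ref.length,):
            raise ValueError(f"depth array length {depth.shape} != genome {ref.length}")
        totals = {b: 0.0 for b in "ACGT"}
        seq = np.frombuffer(ref.sequence.encode(), dtype="S1")
        for b in "ACGT":
            totals[b] = float(depth[seq == b.encode()].sum())
        return cls(animal_id=animal_id, tissue=tissue, depth=depth,
                   nucleotide_depth_totals=totals)

    def at(self, pos: int) -> float:
        return float(self.depth[pos - 1])

    @property
    def mean(self) -> float:
        return float(self.depth.mean())


def read_vcf(path: str | Path, animal_id: str, tissue: str,
             pass_only: bool = True, prefer_af: bool = True) -> list[VariantCall]:
    """Read one single-sample VCF into VariantCalls, one per ALT allele.

    Allele fraction is taken from the sample AF field when present (the
    caller's model estimate), else computed as alt AD / sum(AD); records with
    neither raise.  Multi-allelic records are split.  By default only PASS or
    unfiltered records are kept.
    """
    path = Path(path)
    calls: list[VariantCall] = []
    n_filtered = 0
    with pysam.VariantFile(str(path)) as vf:
        if len(vf.header.samples) != 1:
            raise ValueError(f"{path}: expected exactly one sample column")
        for rec in vf:
            filters = set(rec.filter.keys())
            if pass_only and filters and filters != {"PASS"}:
                n_filtered += 1
                continue
            sample = rec.samples[0]
            af = sample.get("AF") if prefer_af else None
            ad = sample.get("AD")
            dp = sample.get("DP")
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                if af is not None and af[i] is not None:
                    frac = float(af[i])
                elif ad is not None and any(a is not None for a in ad):
                    total = sum(a for a in ad if a is not None)
                    if total <= 0:
                        raise ValueError(f"{path}: zero AD total at pos {rec.pos}")
                    frac = ad[i + 1] / total
                else:
                    raise ValueError(
                        f"{path}: record at pos {rec.pos} has neither AF nor AD"
                    )
                depth = int(dp) if dp is not None else (
                    int(sum(a for a in ad if a is not None)) if ad is not None else 0
                )
                calls.append(
                    VariantCall(
                        animal_id=animal_id,
                        tissue=tissue,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        allele_fraction=frac,
                        depth=depth,
                    )
                )
    logger.info("read %d calls (%d filtered out) from %s", len(calls), n_filtered, path)
    return calls


def read_depth(path: str | Path, ref: MtReference,
               animal_id: str = "", tissue: str = "") -> DepthProfile:
    """Read ``samtools depth`` output (contig, pos, depth).

    Positions absent from the file get depth 0 (samtools omits zero-depth
    sites by default); positions beyond the genome raise.
    """
    path = Path(path)
    depth = np.zeros(ref.length, dtype=float)
    try:
        table = pd.read_csv(path, sep="\t", header=None, comment="#",
                            names=["contig", "pos", "depth"], dtype={"pos": int})
    except pd.errors.EmptyDataError:
        # samtools depth omits zero-depth sites; an empty file is all-zero
        table = pd.DataFrame(columns=["contig", "pos", "depth"])
    if len(table):
        if (table["pos"] < 1).any() or (table["pos"] > ref.length).any():
            bad = table.loc[(table["pos"] < 1) | (table["pos"] > ref.length), "pos"].iloc[0]
            raise ValueError(f"{path}: depth position {bad} outside genome [1, {ref.length}]")
        depth[table["pos"].to_numpy() - 1] = table["depth"].to_numpy(dtype=float)
    return DepthProfile.from_array(animal_id, tissue, depth, ref)


def write_depth(profile: DepthProfile, path: str | Path, contig: str) -> None:
    """Write a three-column depth table (all positions, including zeros)."""
    with open(path, "w") as fh:
        for i, d in enumerate(profile.depth, start=1):
            fh.write(f"{contig}\t{i}\t{int(d)}\n")


# -- classified-mutation table --------------------------------------------

#: Stable column order of the mutation table written by
#: :func:`write_mutation_table` and read back by :func:`read_mutation_table`.
MUTATION_TABLE_COLUMNS = [
    "animal_id", "tissue", "pos", "ref_allele", "alt_allele",
    "allele_fraction", "depth", "var_class", "inheritance", "region",
    "stranded_change", "collapsed_class", "codon_position", "effect",
    "aa_ref", "aa_alt", "property_ref", "property_alt",
    "indel_length", "frameshift", "notes",
]


def variants_to_frame(variants: Sequence) -> pd.DataFrame:
    """Flatten ClassifiedVariant (or VariantCall) records into a DataFrame."""
    rows = []
    for v in variants:
        d = dataclasses.asdict(v)
        if "notes" in d and isinstance(d["notes"], (list, tuple)):
            d["notes"] = ";".join(d["notes"])
        d["indel_length"] = v.indel_length if v.var_class != "SNV" else None
        rows.append(d)
    frame = pd.DataFrame(rows)
    for col in MUTATION_TABLE_COLUMNS:
        if col not in frame.columns:
            frame[col] = pd.NA
    return frame[MUTATION_TABLE_COLUMNS]


def write_mutation_table(variants: Sequence, path: str | Path) -> None:
    """Write classified variants as a TSV, sorted by (animal, tissue, pos)."""
    frame = variants_to_frame(variants)
    frame = frame.sort_values(["animal_id", "tissue", "pos", "alt_allele"],
                              kind="mergesort").reset_index(drop=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    logger.info("wrote %d classified variants to %s", len(frame), path)


def read_mutation_table(path: str | Path) -> list:
    """Read back a mutation table into ClassifiedVariant records."""
    from .classification import ClassifiedVariant  # local import: avoid cycle

    frame = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "tissue": str})
    out = []

    def _opt(value, cast=None):
        if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
            return None
        return cast(value) if cast else value

    for row in frame.itertuples(index=False):
        notes = _opt(row.notes)
        out.append(
            ClassifiedVariant(
                animal_id=row.animal_id,
                tissue=row.tissue,
                pos=int(row.pos),
                ref_allele=row.ref_allele,
                alt_allele=row.alt_allele,
                allele_fraction=float(row.allele_fraction),
                depth=int(row.depth),
                var_class=row.var_class,
                inheritance=_opt(row.inheritance),
                region=_opt(row.region),
                stranded_change=_opt(row.stranded_change),
                collapsed_class=_opt(row.collapsed_class),
                codon_position=_opt(row.codon_position, int),
                effect=_opt(row.effect),
                aa_ref=_opt(row.aa_ref),
                aa_alt=_opt(row.aa_alt),
                property_ref=_opt(row.property_ref),
                property_alt=_opt(row.property_alt),
                frameshift=_opt(row.frameshift, bool),
                notes=tuple(notes.split(";")) if notes else (),
            )
        )
    return out
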