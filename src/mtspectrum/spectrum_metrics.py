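"""Mutation-load metrics and spectrum groupings.

Two metrics quantify heteroplasmic mutation load in a sample:

* mutation count  = (number of bases where a mutation was detected) / length
* mutation frequency = (sum of per-base mutated read fractions) / length

where length is the mt genome length for genome-wide metrics, or the summed
feature length of a region for per-region metrics.  Count measures how many
distinct sites carry any mutation; frequency measures how saturated those
mutations are (a fixed variant contributes 1.0, a 1% heteroplasmy 0.01).

Strand-asymmetry comparisons (e.g. C→T vs G→A on the reference strand) must
correct for nucleotide composition of the reference strand: raw counts from a
source base N are scaled by total_depth(C) / total_depth(N), i.e. all bases
are normalised to cytosine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import COLLAPSED_CLASSES, ClassifiedVariant
from .genome_model import REGION_KINDS, MtReference
from .variant_io import DepthProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpectrumSummary:
    """Count/frequency metrics for one sample slice in one grouping cell."""

    animal_id: str | None
    tissue: str | None
    inheritance: str | None
    grouping: str       # e.g. "region", "effect", "collapsed_class"
    group: str          # the cell label within the grouping
    n_variants: int
    count_metric: float
    frequency_metric: float


def summaries_to_frame(summaries: Iterable[SpectrumSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def mutation_count(variants: Sequence, length: int, mode: str = "bases") -> float:
    """Mutation count metric over an applicable length.

    ``mode='bases'`` counts distinct mutated positions (two different alt
    alleles at one base count once); ``mode='unique'`` counts distinct
    (pos, alt) variants.  The two differ only when one base carries several
    alternate alleles, which is logged.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    bases = {v.pos for v in variants}
    if mode == "bases":
        n = len(bases)
    elif mode == "unique":
        n = len({(v.pos, v.alt_allele) for v in variants})
        if n != len(bases):
            logger.info("unique-variant count %d differs from mutated-base count %d",
                        n, len(bases))
    else:
        raise ValueError(f"unknown counting mode {mode!r}")
    return n / length


def mutation_frequency(variants: Sequence, length: int) -> float:
    """Mutation frequency metric: summed allele fractions / length."""
    if length <= 0:
        raise ValueError("length must be positive")
    return sum(v.allele_fraction for v in variants) / length


def _sample_key(variants: Sequence) -> tuple[str | None, str | None, str | None]:
    def only(values):
        vals = {v for v in values if v is not None}
        return vals.pop() if len(vals) == 1 else None
    return (
        only(v.animal_id for v in variants),
        only(v.tissue for v in variants),
        only(getattr(v, "inheritance", None) for v in variants),
    )


def _cell(variants, grouping, group, length, sample_key, mode="bases") -> SpectrumSummary:
    return SpectrumSummary(
        animal_id=sample_key[0], tissue=sample_key[1], inheritance=sample_key[2],
        grouping=grouping, group=group, n_variants=len(variants),
        count_metric=mutation_count(variants, length, mode=mode) if variants else 0.0,
        frequency_metric=mutation_frequency(variants, length) if variants else 0.0,
    )


def region_metrics(variants: Sequence[ClassifiedVariant], ref: MtReference,
                   mode: str = "bases") -> list[SpectrumSummary]:
    """Per-region count/frequency, denominator = summed region length."""
    lengths = ref.region_lengths()
    key = _sample_key(variants)
    out = []
    for region in (*REGION_KINDS, "intergenic"):
        if lengths[region] == 0:
            out.append(SpectrumSummary(*key, "region", region, 0, 0.0, 0.0))
            continue
        sub = [v for v in variants if v.region == region]
        out.append(_cell(sub, "region", region, lengths[region], key, mode))
    return out


def codon_position_metrics(variants: Sequence[ClassifiedVariant], ref: MtReference,
                           mode: str = "bases") -> list[SpectrumSummary]:
    """Count/frequency per codon position over CDS SNVs.

    The denominator is one third of the complete-codon CDS length: each
    complete codon contributes exactly one first, second and third position.
    Incomplete terminal codons are excluded from both numerator (those SNVs
    are unannotatable) and denominator.
    """
    cds_complete = sum(
        3 * (f.length(ref.length) // 3) for f in ref.features if f.kind == "CDS"
    )
    if cds_complete == 0:
        raise ValueError("reference has no CDS features")
    per_pos_len = cds_complete // 3
    key = _sample_key(variants)
    out = []
    for cp in (1, 2, 3):
        sub = [v for v in variants if v.codon_position == cp]
        out.append(_cell(sub, "codon_position", str(cp), per_pos_len, key, mode))
    return out


def effect_metrics(variants: Sequence[ClassifiedVariant], ref: MtReference,
                   mode: str = "bases") -> list[SpectrumSummary]:
    """Count/frequency per codon effect (silent/missense/nonsense) over the
    combined CDS, denominator = total CDS length."""
    cds_len = ref.region_lengths()["CDS"]
    if cds_len == 0:
        raise ValueError("reference has no CDS features")
    key = _sample_key(variants)
    return [
        _cell([v for v in variants if v.effect == e], "effect", e, cds_len, key, mode)
        for e in ("silent", "missense", "nonsense")
    ]


def substitution_spectrum(variants: Sequence[ClassifiedVariant], length: int,
                          mode: str = "bases") -> list[SpectrumSummary]:
    """Counts/frequencies by the 6 collapsed classes and 12 stranded changes."""
    snvs = [v for v in variants if v.var_class == "SNV"]
    key = _sample_key(variants)
    out = []
    for cls in COLLAPSED_CLASSES:
        sub = [v for v in snvs if v.collapsed_class == cls]
        out.append(_cell(sub, "collapsed_class", cls, length, key, mode))
    stranded_seen = sorted({v.stranded_change for v in snvs if v.stranded_change})
    for change in stranded_seen:
        sub = [v for v in snvs if v.stranded_change == change]
        out.append(_cell(sub, "stranded_change", change, length, key, mode))
    return out


# -- strand-asymmetry nucleotide-bias correction ---------------------------

def correction_factors(depth: DepthProfile) -> dict[str, float]:
    """Per-base correction factors normalised to cytosine.

    factor(N) = total_depth(C) / total_depth(N); factor(C) == 1 exactly.
    """
    totals = depth.nucleotide_depth_totals
    for base in "ACGT":
        if totals.get(base, 0) <= 0:
            raise ValueError(f"zero total depth for nucleotide {base}")
    return {base: totals["C"] / totals[base] for base in "ACGT"}


def reference_composition_factors(ref: MtReference) -> dict[str, float]:
    """Depth-unweighted fallback: factors from reference base counts."""
    counts = {b: ref.sequence.count(b) for b in "ACGT"}
    for base, n in counts.items():
        if n == 0:
            raise ValueError(f"reference contains no {base} bases")
    return {base: counts["C"] / counts[base] for base in "ACGT"}


def strand_bias_correction(
    stranded_counts: Mapping[str, float],
    depth: DepthProfile | None = None,
    ref: MtReference | None = None,
) -> dict[str, float]:
    """Correct stranded substitution counts for nucleotide composition.

    Input maps stranded changes ("G>A") to raw counts.  Each count is scaled
    by the correction factor of its source base, so changes from cytosine are
    unchanged and the six stranded pairs become directly comparable.  Uses
    per-sample depth totals when a DepthProfile is given, else reference base
    composition.
    """
    if depth is not None:
        factors = correction_factors(depth)
    elif ref is not None:
        factors = reference_composition_factors(ref)
    else:
        raise ValueError("need a DepthProfile or an MtReference for correction")
    out = {}
    for change, count in stranded_counts.items():
        source = change.split(">")[0]
        out[change] = count * factors[source]
    return out


# -- rolling genome scan ----------------------------------------------------

@dataclass
class GenomeScan:
    """Per-position mutation tracks with a circular rolling mean.

    ``frequency[i]`` is the mean allele fraction of variants at position i+1
    (0 when none; multiple alts at one base are averaged); ``count[i]`` is a
    0/1 mutated-base indicator.  Rolling means wrap around the origin, and
    the normalised tracks are divided by their own maximum (max 1 whenever
    any signal is present).
    """

    window_bp: int
    frequency: np.ndarray
    count: np.ndarray
    frequency_rolling: np.ndarray = field(default=None)  # type: ignore[assignment]
    count_rolling: np.ndarray = field(default=None)      # type: ignore[assignment]
    frequency_normalized: np.ndarray = field(default=None)  # type: ignore[assignment]
    count_normalized: np.ndarray = field(default=None)      # type: ignore[assignment]


def circular_rolling_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average on a circular track.

    Position i averages the window [i - window//2, i + window - window//2 - 1]
    with indices taken modulo the track length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.asarray(values, dtype=float)
    n = len(values)
    if window > n:
        raise ValueError(f"window {window} exceeds track length {n}")
    left = window // 2
    right = window - left - 1
    extended = np.concatenate([values[n - left:] if left else values[:0],
                               values,
                               values[:right]])
    kernel = np.full(window, 1.0 / window)
    return np.convolve(extended, kernel, mode="valid")


def _normalize(track: np.ndarray) -> np.ndarray:
    peak = track.max()
    return track / peak if peak > 0 else track.copy()


def genome_scan(variants: Sequence, ref: MtReference,
                window_bp: int = 250) -> GenomeScan:
    """Rolling-mean mutation frequency and count tracks across the genome."""
    freq = np.zeros(ref.length)
    nvar = np.zeros(ref.length)
    for v in variants:
        freq[v.pos - 1] += v.allele_fraction
        nvar[v.pos - 1] += 1
    with np.errstate(invalid="ignore"):
        freq = np.where(nvar > 0, freq / np.maximum(nvar, 1), 0.0)
    count = (nvar > 0).astype(float)
    scan = GenomeScan(window_bp=window_bp, frequency=freq, count=count)
    scan.frequency_rolling = circular_rolling_mean(freq, window_bp)
    scan.count_rolling = circular_rolling_mean(count, window_bp)
    scan.frequency_normalized = _normalize(scan.frequency_rolling)
    scan.count_normalized = _normalize(scan.count_rolling)
    return scan


def write_bedgraph(scan: GenomeScan, contig: str, path: str | Path,
                   track: str = "frequency_normalized") -> None:
    """Write a scan track as 4-column BedGraph text (0-based half-open)."""
    values = getattr(scan, track)
    with open(path, "w") as fh:
        for i, val in enumerate(values):
            fh.write(f"{contig}\t{i}\t{i + 1}\t{val:.6g}\n")


def plot_genome_scan(scan: GenomeScan, ax=None, title: str | None = None):
    """Plot the normalised frequency and count rolling tracks."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(1, len(scan.frequency_normalized) + 1)
    ax.plot(x, scan.frequency_normalized, label="frequency (normalised)", lw=1)
    ax.plot(x, scan.count_normalized, label="count (normalised)", lw=1)
    ax.set_xlabel("mtDNA position (bp)")
    ax.set_ylabel(f"rolling mean ({scan.window_bp} bp), x/max(x)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    return ax
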