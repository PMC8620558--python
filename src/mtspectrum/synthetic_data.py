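"""Synthetic paired-tissue heteroplasmic variant cohorts.

Generates, at the variant-call level (no reads, no aligner), the data
structure the analysis pipeline consumes: per-animal brain/liver VCFs with
germline (shared, higher-frequency) and somatic (tissue-private,
lower-frequency) variants, per-base depth tables, and a truth table of every
injected parameter realisation.

The default configuration mirrors a mutator-mouse cohort: 14 animals,
~160 germline variants per animal plus tissue-specific somatic loads
(liver carrying several times more than brain), a C:T/G:A-dominated
substitution spectrum (3x the T:C/A:G class), five-fold D-loop depletion,
germline transmission biased against missense changes, mostly short
frameshift deletions among indels, and ~8200x mean coverage.  Every draw is
driven by one seed; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .classification import COLLAPSED_CLASSES, annotate_effect, classify_substitution
from .genome_model import COMPLEMENT, Feature, MtReference
from .variant_io import DepthProfile, VariantCall, write_depth

logger = logging.getLogger(__name__)

TISSUES = ("brain", "liver")

#: Default collapsed-class weights: transitions dominate, with the
#: replication-error C:T/G:A class three times the T:C/A:G class and the
#: C:G/G:C and T:G/A:C transversions rare.
DEFAULT_SPECTRUM_WEIGHTS = {
    "C:T/G:A": 0.60,
    "T:C/A:G": 0.20,
    "C:A/G:T": 0.075,
    "T:A/A:T": 0.075,
    "C:G/G:C": 0.025,
    "T:G/A:C": 0.025,
}

#: L-strand-like base composition for non-coding synthetic sequence
#: (A-rich, C about twice G, as in mouse mtDNA).
BASE_COMPOSITION = {"A": 0.345, "C": 0.244, "G": 0.121, "T": 0.290}

# (name, kind, length, strand) in mouse mtDNA gene order; CDS lengths are
# multiples of 3 so every gene has complete codons.
_MOUSE_LAYOUT = [
    ("tRNA-Phe", "tRNA", 70, "+"),
    ("12S-rRNA", "rRNA", 955, "+"),
    ("tRNA-Val", "tRNA", 70, "+"),
    ("16S-rRNA", "rRNA", 1580, "+"),
    ("tRNA-Leu1", "tRNA", 75, "+"),
    ("ND1", "CDS", 957, "+"),
    ("tRNA-Ile", "tRNA", 70, "+"),
    ("tRNA-Gln", "tRNA", 70, "-"),
    ("tRNA-Met", "tRNA", 70, "+"),
    ("ND2", "CDS", 1038, "+"),
    ("tRNA-Trp", "tRNA", 70, "+"),
    ("tRNA-Ala", "tRNA", 70, "-"),
    ("tRNA-Asn", "tRNA", 70, "-"),
    ("tRNA-Cys", "tRNA", 65, "-"),
    ("tRNA-Tyr", "tRNA", 70, "-"),
    ("COX1", "CDS", 1545, "+"),
    ("tRNA-Ser1", "tRNA", 70, "-"),
    ("tRNA-Asp", "tRNA", 70, "+"),
    ("COX2", "CDS", 684, "+"),
    ("tRNA-Lys", "tRNA", 70, "+"),
    ("ATP8", "CDS", 204, "+"),
    ("ATP6", "CDS", 681, "+"),
    ("COX3", "CDS", 783, "+"),
    ("tRNA-Gly", "tRNA", 70, "+"),
    ("ND3", "CDS", 348, "+"),
    ("tRNA-Arg", "tRNA", 70, "+"),
    ("ND4L", "CDS", 297, "+"),
    ("ND4", "CDS", 1377, "+"),
    ("tRNA-His", "tRNA", 70, "+"),
    ("tRNA-Ser2", "tRNA", 60, "+"),
    ("tRNA-Leu2", "tRNA", 75, "+"),
    ("ND5", "CDS", 1824, "+"),
    ("ND6", "CDS", 519, "-"),
    ("tRNA-Glu", "tRNA", 70, "-"),
    ("CYTB", "CDS", 1143, "+"),
    ("tRNA-Thr", "tRNA", 70, "+"),
    ("tRNA-Pro", "tRNA", 70, "-"),
    ("D-loop", "D-loop", 880, "+"),
]

_STOP_CODONS_TABLE2 = {"TAA", "TAG", "AGA", "AGG"}


def _random_bases(rng: np.random.Generator, n: int) -> str:
    bases = np.array(list("ACGT"))
    probs = np.array([BASE_COMPOSITION[b] for b in "ACGT"])
    probs = probs / probs.sum()
    return "".join(rng.choice(bases, size=n, p=probs))


def _random_coding(rng: np.random.Generator, n_bp: int) -> str:
    """ATG + random internal non-stop codons + TAA, n_bp a multiple of 3."""
    assert n_bp % 3 == 0 and n_bp >= 9
    codons = ["ATG"]
    while len(codons) < n_bp // 3 - 1:
        cod = _random_bases(rng, 3)
        if cod not in _STOP_CODONS_TABLE2:
            codons.append(cod)
    codons.append("TAA")
    return "".join(codons)


def mouse_like_reference(seed: int = 91166, contig: str = "chrM_synthetic") -> MtReference:
    """Deterministic synthetic mtDNA reference with a mouse-like layout.

    Synthetic stand-in for a real mouse mitochondrial genome: same gene
    order, kinds, strands and approximate lengths, an L-strand-like base
    composition (C roughly twice G), and stop-free reading frames — but a
    random sequence, not mm10.
    """
    rng = np.random.default_rng(seed)
    seq_parts: list[str] = []
    features: list[Feature] = []
    cursor = 1
    for name, kind, length, strand in _MOUSE_LAYOUT:
        gap = int(rng.integers(1, 4))
        seq_parts.append(_random_bases(rng, gap))
        cursor += gap
        if kind == "CDS":
            coding = _random_coding(rng, length)
            ref_seq = coding if strand == "+" else "".join(
                COMPLEMENT[b] for b in reversed(coding)
            )
        else:
            ref_seq = _random_bases(rng, length)
        seq_parts.append(ref_seq)
        features.append(Feature(name=name, kind=kind, start=cursor,
                                end=cursor + length - 1, strand=strand))
        cursor += length
    seq_parts.append(_random_bases(rng, int(rng.integers(1, 4))))
    return MtReference(name=contig, sequence="".join(seq_parts), features=features)


@dataclass
class SimConfig:
    """Cohort generator settings; the seed fully determines the output."""

    seed: int = 0
    n_animals: int = 14
    genome: MtReference | None = None
    n_germline: int = 160          # per animal (shared by both tissues)
    #: somatic variants per tissue: an int (same load in both tissues) or a
    #: {"brain": n, "liver": n} map; the default mirrors the roughly twofold
    #: higher mutation load of liver over brain in mutator mice
    n_somatic: int | dict = field(
        default_factory=lambda: {"brain": 40, "liver": 240})
    spectrum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM_WEIGHTS))
    germline_af: tuple = ("beta", 1.5, 6.0)   # mean 0.20
    somatic_af: tuple = ("beta", 1.0, 12.0)   # mean 0.077
    dloop_depletion: float = 0.2   # multiplier on per-base mutation probability
    missense_germline_penalty: float = 0.5    # transmission probability multiplier
    indel_fraction: float = 0.15
    indel_length_p: float = 0.68   # geometric(p): short indels, ~7% in-frame
    deletion_bias: float = 0.85
    mean_depth: float = 8200.0
    #: "poisson" draws each animal's germline/somatic counts around the
    #: configured means (animals genuinely differ, as in real cohorts);
    #: "fixed" injects the exact numbers
    count_model: str = "poisson"

    def __post_init__(self) -> None:
        total = sum(self.spectrum_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum weights sum to {total}, expected 1")
        if set(self.spectrum_weights) != set(COLLAPSED_CLASSES):
            raise ValueError("spectrum weights must cover the 6 collapsed classes")
        for name in ("dloop_depletion", "missense_germline_penalty",
                     "indel_fraction", "indel_length_p", "deletion_bias"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if isinstance(self.n_somatic, dict) and set(self.n_somatic) != set(TISSUES):
            raise ValueError(f"n_somatic map must have keys {TISSUES}")
        if self.count_model not in ("poisson", "fixed"):
            raise ValueError(f"unknown count_model {self.count_model!r}")

    def somatic_per_tissue(self) -> dict[str, int]:
        if isinstance(self.n_somatic, dict):
            return {t: int(self.n_somatic[t]) for t in TISSUES}
        return {t: int(self.n_somatic) for t in TISSUES}

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genome"] = None if self.genome is None else self.genome.name
        return d


@dataclass
class SimulatedCohort:
    ref: MtReference
    config: SimConfig
    calls: dict[tuple[str, str], list[VariantCall]]
    depths: dict[tuple[str, str], DepthProfile]
    truth: pd.DataFrame


# -- internal draws ---------------------------------------------------------

_CLASS_SOURCES = {cls: (cls[0], COMPLEMENT[cls[0]]) for cls in COLLAPSED_CLASSES}
_CLASS_TARGETS = {cls: {cls[0]: cls[2], COMPLEMENT[cls[0]]: COMPLEMENT[cls[2]]}
                  for cls in COLLAPSED_CLASSES}

_MAX_TRIES = 200_000


class _SiteSampler:
    """Rejection sampler for mutation sites on a reference genome."""

    def __init__(self, ref: MtReference, dloop_depletion: float,
                 rng: np.random.Generator):
        self.ref = ref
        self.rng = rng
        self.depletion = dloop_depletion
        seq = np.frombuffer(ref.sequence.encode(), dtype="S1")
        self.by_base = {
            b: np.flatnonzero(seq == b.encode()) + 1 for b in "ACGT"
        }
        labels = [ref.region_of(p) for p in range(1, ref.length + 1)]
        self.is_dloop = np.array([lab == "D-loop" for lab in labels])
        self.by_class = {
            cls: np.concatenate([self.by_base[b] for b in _CLASS_SOURCES[cls]])
            for cls in COLLAPSED_CLASSES
        }

    def _accept_region(self, pos: int) -> bool:
        if not self.is_dloop[pos - 1]:
            return True
        return self.rng.random() < self.depletion

    def snv_site(self, collapsed_class: str, used: set[int]) -> int:
        candidates = self.by_class[collapsed_class]
        for _ in range(_MAX_TRIES):
            pos = int(candidates[self.rng.integers(len(candidates))])
            if pos in used:
                continue
            if self._accept_region(pos):
                return pos
        raise RuntimeError(
            f"could not place a {collapsed_class} variant: requested mutations "
            "exceed available sites"
        )

    def indel_site(self, span: int, used: set[int]) -> int:
        for _ in range(_MAX_TRIES):
            pos = int(self.rng.integers(1, self.ref.length - span + 1))
            if any(p in used for p in range(pos, pos + span + 1)):
                continue
            if self._accept_region(pos):
                return pos
        raise RuntimeError("could not place an indel: requested mutations exceed "
                           "available sites")


def _draw_af(spec: tuple, rng: np.random.Generator) -> float:
    family = spec[0]
    if family == "beta":
        af = float(rng.beta(spec[1], spec[2]))
    elif family == "fixed":
        af = float(spec[1])
    else:
        raise ValueError(f"unknown AF distribution family {spec[0]!r}")
    af = min(max(round(af, 4), 1e-4), 1.0)
    return af


def _snv_effect(ref: MtReference, pos: int, ref_base: str, alt_base: str) -> str | None:
    probe = VariantCall(animal_id="", tissue="brain", pos=pos, ref_allele=ref_base,
                        alt_allele=alt_base, allele_fraction=0.5, depth=1)
    return annotate_effect(probe, ref)["effect"]


def _draw_variant(sampler: _SiteSampler, config: SimConfig,
                  rng: np.random.Generator, used: set[int],
                  germline: bool) -> dict:
    """One injected mutation: site, alleles, class, effect, frameshift."""
    ref = sampler.ref
    classes = list(config.spectrum_weights)
    weights = np.array([config.spectrum_weights[c] for c in classes])
    if rng.random() < config.indel_fraction:
        length = int(rng.geometric(config.indel_length_p))
        is_deletion = rng.random() < config.deletion_bias
        span = length if is_deletion else 0
        pos = sampler.indel_site(span, used)
        anchor = ref.base(pos)
        if is_deletion:
            ref_allele = ref.sequence[pos - 1: pos + length]
            alt_allele = anchor
        else:
            ref_allele = anchor
            alt_allele = anchor + _random_bases(rng, length)
        for p in range(pos, pos + span + 1):
            used.add(p)
        return {
            "pos": pos, "ref": ref_allele, "alt": alt_allele,
            "var_class": "deletion" if is_deletion else "insertion",
            "collapsed_class": None, "stranded_change": None,
            "effect": None, "indel_length": length,
            "frameshift": length % 3 != 0,
            "region": ref.region_of(pos),
        }
    for _ in range(_MAX_TRIES):
        cls = classes[int(rng.choice(len(classes), p=weights))]
        pos = sampler.snv_site(cls, used)
        ref_base = ref.base(pos)
        alt_base = _CLASS_TARGETS[cls][ref_base]
        effect = _snv_effect(ref, pos, ref_base, alt_base)
        if (germline and effect == "missense"
                and rng.random() >= config.missense_germline_penalty):
            continue  # missense change rejected by the germline sieve
        used.add(pos)
        stranded, collapsed = classify_substitution(ref_base, alt_base)
        return {
            "pos": pos, "ref": ref_base, "alt": alt_base,
            "var_class": "SNV", "collapsed_class": collapsed,
            "stranded_change": stranded, "effect": effect,
            "indel_length": None, "frameshift": None,
            "region": ref.region_of(pos),
        }
    raise RuntimeError("could not draw an SNV: requested mutations exceed "
                       "available sites")


def _simulate_animal(animal_id: str, sampler: _SiteSampler, config: SimConfig,
                     rng: np.random.Generator,
                     n_germline: int, n_somatic: dict[str, int],
                     depths: dict[str, DepthProfile]):
    used: set[int] = set()
    calls: dict[str, list[VariantCall]] = {t: [] for t in TISSUES}
    truth_rows: list[dict] = []

    def record(tissue: str, draw: dict, af: float, inheritance: str) -> None:
        depth_here = int(depths[tissue].at(draw["pos"]))
        calls[tissue].append(VariantCall(
            animal_id=animal_id, tissue=tissue, pos=draw["pos"],
            ref_allele=draw["ref"], alt_allele=draw["alt"],
            allele_fraction=af, depth=depth_here,
        ))
        truth_rows.append({
            "animal_id": animal_id, "tissue": tissue, "inheritance": inheritance,
            "pos": draw["pos"], "ref_allele": draw["ref"], "alt_allele": draw["alt"],
            "allele_fraction": af, "var_class": draw["var_class"],
            "collapsed_class": draw["collapsed_class"],
            "stranded_change": draw["stranded_change"],
            "effect": draw["effect"], "region": draw["region"],
            "indel_length": draw["indel_length"], "frameshift": draw["frameshift"],
        })

    for _ in range(n_germline):
        draw = _draw_variant(sampler, config, rng, used, germline=True)
        for tissue in TISSUES:
            record(tissue, draw, _draw_af(config.germline_af, rng), "germline")
    for tissue in TISSUES:
        for _ in range(n_somatic[tissue]):
            draw = _draw_variant(sampler, config, rng, used, germline=False)
            record(tissue, draw, _draw_af(config.somatic_af, rng), "somatic")
    for tissue in TISSUES:
        calls[tissue].sort(key=lambda c: (c.pos, c.alt_allele))
    return calls, truth_rows


def _check_capacity(config: SimConfig, ref: MtReference) -> None:
    needed = config.n_germline + sum(config.somatic_per_tissue().values())
    if needed > ref.length:
        raise ValueError(
            f"requested {needed} mutations per animal exceed the "
            f"{ref.length} available sites"
        )


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Simulate a paired-tissue cohort under the configured generative model.

    Germline variants are drawn once per animal and copied to both tissues
    with tissue-specific allele fractions; somatic variants are drawn
    independently per tissue.  Site choice respects the D-loop depletion
    multiplier; the substitution class is multinomial over the spectrum
    weights, with the stranded direction set by the reference base at the
    chosen site.  Positions are not reused within an animal, so no somatic
    pair can masquerade as germline.
    """
    rng = np.random.default_rng(config.seed)
    ref = config.genome or mouse_like_reference()
    _check_capacity(config, ref)
    sampler = _SiteSampler(ref, config.dloop_depletion, rng)
    calls: dict[tuple[str, str], list[VariantCall]] = {}
    depths: dict[tuple[str, str], DepthProfile] = {}
    truth_rows: list[dict] = []
    for i in range(config.n_animals):
        animal_id = f"A{i + 1:02d}"
        animal_depths = {
            t: DepthProfile.from_array(
                animal_id, t, rng.poisson(config.mean_depth, ref.length), ref)
            for t in TISSUES
        }
        somatic_means = config.somatic_per_tissue()
        if config.count_model == "poisson":
            n_germline = int(rng.poisson(config.n_germline))
            n_somatic = {t: int(rng.poisson(somatic_means[t])) for t in TISSUES}
        else:
            n_germline = config.n_germline
            n_somatic = somatic_means
        animal_calls, rows = _simulate_animal(
            animal_id, sampler, config, rng,
            n_germline=n_germline,
            n_somatic=n_somatic,
            depths=animal_depths,
        )
        for t in TISSUES:
            calls[(animal_id, t)] = animal_calls[t]
            depths[(animal_id, t)] = animal_depths[t]
        truth_rows.extend(rows)
    truth = pd.DataFrame(truth_rows)
    logger.info("simulated %d animals, %d call records", config.n_animals, len(truth))
    return SimulatedCohort(ref=ref, config=config, calls=calls, depths=depths,
                           truth=truth)


def null_cohort(config: SimConfig, rate: float = 3.0) -> SimulatedCohort:
    """Wild-type-like control: no germline variants, Poisson(rate) somatic
    variants per sample.  rate=0 gives completely mutation-free samples."""
    rng = np.random.default_rng(config.seed)
    ref = config.genome or mouse_like_reference()
    sampler = _SiteSampler(ref, config.dloop_depletion, rng)
    calls: dict[tuple[str, str], list[VariantCall]] = {}
    depths: dict[tuple[str, str], DepthProfile] = {}
    truth_rows: list[dict] = []
    for i in range(config.n_animals):
        animal_id = f"W{i + 1:02d}"
        animal_depths = {
            t: DepthProfile.from_array(
                animal_id, t, rng.poisson(config.mean_depth, ref.length), ref)
            for t in TISSUES
        }
        n_somatic = {t: int(rng.poisson(rate)) for t in TISSUES}
        animal_calls, rows = _simulate_animal(
            animal_id, sampler, config, rng,
            n_germline=0, n_somatic=n_somatic, depths=animal_depths,
        )
        for t in TISSUES:
            calls[(animal_id, t)] = animal_calls[t]
            depths[(animal_id, t)] = animal_depths[t]
        truth_rows.extend(rows)
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(ref=ref, config=config, calls=calls, depths=depths,
                           truth=truth)


# -- emission ----------------------------------------------------------------

def _vcf_header(ref: MtReference, sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.contigs.add(ref.name, length=ref.length)
    header.formats.add("AF", "A", "Float", "Allele fraction of the alternate allele")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.formats.add("DP", "1", "Integer", "Read depth")
    header.add_sample(sample)
    return header


def write_vcf(calls: list[VariantCall], ref: MtReference, path: str | Path) -> None:
    """Write one sample's calls as a VCF 4.2 file (PASS, AF/AD/DP fields)."""
    if not calls:
        sample = "sample"
    else:
        sample = f"{calls[0].animal_id}_{calls[0].tissue}"
    header = _vcf_header(ref, sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for call in sorted(calls, key=lambda c: (c.pos, c.alt_allele)):
            rec = vf.new_record(
                contig=ref.name, start=call.pos - 1,
                alleles=(call.ref_allele, call.alt_allele),
            )
            dp = max(call.depth, 1)
            alt_ad = int(round(call.allele_fraction * dp))
            rec.samples[sample]["AF"] = call.allele_fraction
            rec.samples[sample]["AD"] = (dp - alt_ad, alt_ad)
            rec.samples[sample]["DP"] = dp
            rec.filter.add("PASS")
            vf.write(rec)


def write_reference(ref: MtReference, fasta_path: str | Path,
                    gff_path: str | Path) -> None:
    """Write the reference FASTA (70-col wrap) and its GFF annotation."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, ref.length, 70):
            fh.write(ref.sequence[i:i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in ref.features:
            fh.write("\t".join([
                ref.name, "mtspectrum", f.kind, str(f.start), str(f.end),
                ".", f.strand, ".", f"Name={f.name}",
            ]) + "\n")


def emit(cohort: SimulatedCohort, outdir: str | Path) -> dict:
    """Write a run directory: per-sample VCFs and depth tables, the truth
    TSV, the reference FASTA/GFF, and a manifest.  Returns the manifest."""
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    (outdir / "depth").mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cohort.config.to_dict(),
        "contig": cohort.ref.name,
        "genome_length": cohort.ref.length,
        "samples": [],
    }
    write_reference(cohort.ref, outdir / "reference.fa", outdir / "annotation.gff")
    for (animal_id, tissue), calls in sorted(cohort.calls.items()):
        vcf_path = outdir / "vcf" / f"{animal_id}_{tissue}.vcf"
        depth_path = outdir / "depth" / f"{animal_id}_{tissue}.depth.tsv"
        write_vcf(calls, cohort.ref, vcf_path)
        write_depth(cohort.depths[(animal_id, tissue)], depth_path, cohort.ref.name)
        manifest["samples"].append({
            "animal_id": animal_id, "tissue": tissue,
            "vcf": str(vcf_path.relative_to(outdir)),
            "depth": str(depth_path.relative_to(outdir)),
            "n_calls": len(calls),
        })
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest["truth"] = "truth.tsv"
    manifest["reference"] = "reference.fa"
    manifest["annotation"] = "annotation.gff"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("emitted cohort to %s (%d samples)", outdir, len(manifest["samples"]))
    return manifest
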