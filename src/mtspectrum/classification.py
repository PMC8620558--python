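"""Mutation taxonomy: germline/somatic pairing, substitution classes,
codon effects, amino-acid property changes, and frameshift status.

A heteroplasmic variant is *germline* when the identical change — same base,
same nucleotide substitution — is detected in both tissues (brain and liver)
of the same animal, and *somatic* when it appears in only one tissue.  No
allele-fraction similarity is required; detection thresholds live upstream in
the caller, and independent recurrence of the same change in both tissues is
knowingly counted as germline.

Single-base substitutions collapse 2-to-1 into six classes because a change
and its reverse-complement partner are indistinguishable in double-stranded
sequencing data (e.g. C→A on the reference strand is the same molecular event
as G→T).  The stranded direction is preserved separately for the
strand-asymmetry analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .genome_model import (
    COMPLEMENT,
    IncompleteCodonError,
    MtReference,
    aa_property,
    codon_context,
    translate,
)
from .variant_io import VariantCall

logger = logging.getLogger(__name__)

#: The six collapsed substitution classes (pyrimidine-first labels).
COLLAPSED_CLASSES = (
    "C:T/G:A", "T:C/A:G", "C:A/G:T", "T:A/A:T", "C:G/G:C", "T:G/A:C",
)

#: All 12 stranded single-base changes, as "R>A" strings.
STRANDED_CHANGES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)

EFFECTS = ("silent", "missense", "nonsense", "noncoding")


def classify_substitution(ref_allele: str, alt_allele: str) -> tuple[str, str]:
    """(stranded change, collapsed class) for a single-base substitution.

    The collapsed label puts the pyrimidine-source member first, so applying
    the collapse to either member of a reverse-complement pair yields the
    same label (idempotent by construction).
    """
    r, a = ref_allele.upper(), alt_allele.upper()
    if r not in "ACGT" or a not in "ACGT" or len(r) != 1 or len(a) != 1:
        raise ValueError(f"not a single-base substitution: {ref_allele!r}>{alt_allele!r}")
    if r == a:
        raise ValueError(f"identical alleles: {r!r}")
    stranded = f"{r}>{a}"
    if r in "CT":
        pr, pa = r, a
    else:
        pr, pa = COMPLEMENT[r], COMPLEMENT[a]
    collapsed = f"{pr}:{pa}/{COMPLEMENT[pr]}:{COMPLEMENT[pa]}"
    return stranded, collapsed


@dataclass(frozen=True)
class ClassifiedVariant(VariantCall):
    """A VariantCall with the full mutation taxonomy attached.

    ``codon_position``, ``effect``, ``aa_ref``/``aa_alt`` and the property
    pair are None outside CDS (and for indels); ``frameshift`` is defined for
    indels only.  ``notes`` records annotation flags (e.g. unannotatable
    terminal codons, non-CDS frameshift calls).
    """

    inheritance: str | None = None          # germline | somatic
    region: str | None = None               # CDS | tRNA | rRNA | D-loop | intergenic
    stranded_change: str | None = None      # e.g. "G>A" (SNVs)
    collapsed_class: str | None = None      # one of COLLAPSED_CLASSES (SNVs)
    codon_position: int | None = None
    effect: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    property_ref: str | None = None
    property_alt: str | None = None
    frameshift: bool | None = None
    notes: tuple[str, ...] = ()

    @classmethod
    def from_call(cls, call: VariantCall, **fields) -> "ClassifiedVariant":
        return cls(
            animal_id=call.animal_id,
            tissue=call.tissue,
            pos=call.pos,
            ref_allele=call.ref_allele,
            alt_allele=call.alt_allele,
            allele_fraction=call.allele_fraction,
            depth=call.depth,
            var_class=call.var_class,
            **fields,
        )


def pair_tissues(
    brain_calls: Sequence[VariantCall], liver_calls: Sequence[VariantCall]
) -> list[ClassifiedVariant]:
    """Label one animal's calls germline/somatic by brain–liver intersection.

    A variant is germline iff an identical (pos, ref, alt) tuple exists in
    both tissues; all others are somatic.  Germline variants appear twice in
    the output (once per tissue) so tissue-level frequency metrics remain
    computable even though the count metric cannot separate tissues for
    germline mutations.
    """
    animals = {c.animal_id for c in (*brain_calls, *liver_calls)}
    if len(animals) > 1:
        raise ValueError(f"pair_tissues got calls from multiple animals: {sorted(animals)}")
    brain_keys = {c.key for c in brain_calls}
    liver_keys = {c.key for c in liver_calls}
    shared = brain_keys & liver_keys
    out = []
    for call in (*brain_calls, *liver_calls):
        label = "germline" if call.key in shared else "somatic"
        out.append(ClassifiedVariant.from_call(call, inheritance=label))
    return out


def annotate_effect(v: VariantCall, ref: MtReference) -> dict:
    """Codon-effect fields for an SNV: codon_position, effect, aa_ref, aa_alt.

    Non-CDS positions get effect 'noncoding'.  Inside a CDS the reference
    codon is mutated at the variant position (complementing the alt allele
    for '-'-strand genes), both codons are translated under the vertebrate
    mitochondrial code, and the change is silent / missense / nonsense.
    Positions in an incomplete terminal codon are logged and returned
    unannotatable (effect None, note set).
    """
    if v.var_class != "SNV":
        raise ValueError("annotate_effect applies to SNVs only")
    region = ref.region_of(v.pos)
    if region != "CDS":
        return {"region": region, "codon_position": None, "effect": "noncoding",
                "aa_ref": None, "aa_alt": None, "notes": ()}
    try:
        ctx = codon_context(ref, v.pos)
    except IncompleteCodonError as exc:
        logger.warning("unannotatable SNV at pos %d: %s", v.pos, exc)
        return {"region": region, "codon_position": None, "effect": None,
                "aa_ref": None, "aa_alt": None,
                "notes": ("incomplete_terminal_codon",)}
    alt_base = v.alt_allele if ctx.feature.strand == "+" else COMPLEMENT[v.alt_allele]
    idx = ctx.codon_position - 1
    if ctx.codon[idx] != (v.ref_allele if ctx.feature.strand == "+"
                          else COMPLEMENT[v.ref_allele]):
        logger.warning("reference mismatch at pos %d: codon %s vs ref allele %s",
                       v.pos, ctx.codon, v.ref_allele)
        return {"region": region, "codon_position": ctx.codon_position, "effect": None,
                "aa_ref": None, "aa_alt": None, "notes": ("reference_mismatch",)}
    alt_codon = ctx.codon[:idx] + alt_base + ctx.codon[idx + 1:]
    aa_ref = translate(ctx.codon)
    aa_alt = translate(alt_codon)
    if aa_ref == aa_alt:
        effect = "silent"
    elif aa_alt == "*" and aa_ref != "*":
        effect = "nonsense"
    else:
        effect = "missense"
    return {"region": region, "codon_position": ctx.codon_position, "effect": effect,
            "aa_ref": aa_ref, "aa_alt": aa_alt, "notes": ()}


def annotate_property_change(
    aa_ref: str, aa_alt: str, property_map: Mapping[str, str] | None = None
) -> tuple[str, str]:
    """Ordered (reference, variant) amino-acid property classes."""
    return aa_property(aa_ref, property_map), aa_property(aa_alt, property_map)


def classify_indel(v: VariantCall) -> tuple[str, int, bool]:
    """(direction, length, frameshift) for an indel.

    Frameshift iff the inserted/deleted length is not a multiple of three.
    Frameshift status is computed for all indels but only biologically
    meaningful inside CDS; callers flag non-CDS cases.
    """
    if v.var_class == "SNV":
        raise ValueError("classify_indel applies to indels only")
    length = v.indel_length
    return v.var_class, length, length % 3 != 0


def annotate_variant(cv: ClassifiedVariant, ref: MtReference) -> ClassifiedVariant:
    """Fill region, substitution, codon-effect, property and indel fields."""
    region = ref.region_of(cv.pos)
    if cv.var_class == "SNV":
        stranded, collapsed = classify_substitution(cv.ref_allele, cv.alt_allele)
        eff = annotate_effect(cv, ref)
        prop_ref = prop_alt = None
        if eff["aa_ref"] is not None and eff["aa_alt"] is not None:
            prop_ref, prop_alt = annotate_property_change(eff["aa_ref"], eff["aa_alt"])
        return replace(
            cv,
            region=region,
            stranded_change=stranded,
            collapsed_class=collapsed,
            codon_position=eff["codon_position"],
            effect=eff["effect"],
            aa_ref=eff["aa_ref"],
            aa_alt=eff["aa_alt"],
            property_ref=prop_ref,
            property_alt=prop_alt,
            notes=cv.notes + tuple(eff["notes"]),
        )
    _, _, frameshift = classify_indel(cv)
    notes = cv.notes
    if frameshift and region != "CDS":
        notes = notes + ("frameshift_outside_cds",)
    return replace(cv, region=region, frameshift=frameshift, notes=notes)


def classify_variants(
    brain_calls: Sequence[VariantCall],
    liver_calls: Sequence[VariantCall],
    ref: MtReference,
) -> list[ClassifiedVariant]:
    """Full per-animal classification: tissue pairing plus annotation."""
    return [annotate_variant(cv, ref) for cv in pair_tissues(brain_calls, liver_calls)]
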