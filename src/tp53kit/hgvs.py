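"""Parse, normalize and classify HGVS c. variant descriptions.

Supported grammar (a deliberate subset of HGVS, covering everything the
cohort tables contain): substitutions ``NNN[+/-off]R>A``, deletions
``NNN[_MMM]del[seq]``, duplications ``NNN[_MMM]dup[seq]``, insertions
``NNN_MMMins<seq>`` and ``NNN[_MMM]delins<seq>``.  Protein (p.) and genomic
(g.) descriptions are produced elsewhere, never consumed.  Only the major
transcript handled by the :class:`~tp53kit.reference.GeneModel` is
supported; descriptions carrying a different transcript prefix are
rejected.

Substitutions collapse onto the six strand-symmetric event classes
(GC>AT, AT>GC, GC>TA, GC>CG, AT>TA, AT>CG) used for mutation-spectrum
analysis, with a CpG flag for the deamination-associated C>T/G>A changes
at CG dinucleotides.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, replace

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .errors import (
    CoordinateError,
    HgvsParseError,
    ReferenceMismatchError,
    UnsupportedHgvsError,
)
from .reference import GeneModel, SpliceSignal, cdna_to_codon, signal_at

VAR_CLASSES = (
    "missense",
    "nonsense",
    "synonymous",
    "frameshift",
    "inframe_indel",
    "splice",
    "intronic_other",
)

# strand-symmetric substitution event classes, keyed by (ref, alt)
EVENT_CLASSES = ("GC>AT", "AT>GC", "GC>TA", "GC>CG", "AT>TA", "AT>CG")
_EVENT_OF = {
    ("C", "T"): "GC>AT", ("G", "A"): "GC>AT",
    ("T", "C"): "AT>GC", ("A", "G"): "AT>GC",
    ("C", "A"): "GC>TA", ("G", "T"): "GC>TA",
    ("C", "G"): "GC>CG", ("G", "C"): "GC>CG",
    ("T", "A"): "AT>TA", ("A", "T"): "AT>TA",
    ("T", "G"): "AT>CG", ("A", "C"): "AT>CG",
}

_PREFIX_RE = re.compile(r"^(?:NM_\d+(?:\.\d+)?[_:])?(?:c\.)?")
_POS = r"(\d+)([+-]\d+)?"
_SUB_RE = re.compile(rf"^{_POS}([ACGT])>([ACGT])$")
_RANGE = rf"{_POS}(?:_{_POS})?"
_DEL_RE = re.compile(rf"^{_RANGE}del([ACGT]*)$")
_DUP_RE = re.compile(rf"^{_RANGE}dup([ACGT]*)$")
_INS_RE = re.compile(rf"^{_POS}_{_POS}ins([ACGT]+)$")
_DELINS_RE = re.compile(rf"^{_RANGE}delins([ACGT]+)$")
_UNSUPPORTED = ("inv", "ext", "con", "=/", "[", "(;)")


@dataclass(frozen=True)
class CodingVariant:
    """A parsed HGVS c. description on the model transcript."""

    raw: str
    kind: str  # substitution | deletion | insertion | duplication | delins
    start: int  # anchor cDNA coordinate
    start_offset: int = 0  # signed intronic offset; 0 when exonic
    end: int | None = None  # for ranged variants (deletion/dup/ins/delins)
    end_offset: int = 0
    ref: str = ""  # stated reference allele ("" when not stated)
    alt: str = ""  # inserted / substituted sequence

    @property
    def is_intronic(self) -> bool:
        return self.start_offset != 0 or self.end_offset != 0

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end if self.end is not None else self.start

    def __str__(self) -> str:  # canonical form
        return format_hgvs_c(self)


def _format_pos(anchor: int, offset: int) -> str:
    if offset == 0:
        return str(anchor)
    return f"{anchor}{offset:+d}"


def format_hgvs_c(v: CodingVariant) -> str:
    """Canonical string for a parsed variant; always "c."-prefixed.

    Deleted/duplicated sequences are omitted per current HGVS preference,
    so ``parse("c.626_627delAG")`` formats as ``c.626_627del``.
    """
    left = _format_pos(v.start, v.start_offset)
    span = left
    if v.end is not None and (v.end, v.end_offset) != (v.start, v.start_offset):
        span = f"{left}_{_format_pos(v.end, v.end_offset)}"
    if v.kind == "substitution":
        return f"c.{left}{v.ref}>{v.alt}"
    if v.kind == "deletion":
        return f"c.{span}del"
    if v.kind == "duplication":
        return f"c.{span}dup"
    if v.kind == "insertion":
        return f"c.{span}ins{v.alt}"
    if v.kind == "delins":
        return f"c.{span}delins{v.alt}"
    raise ValueError(f"unknown variant kind {v.kind!r}")


def _parse_offset(text: str | None) -> int:
    return int(text) if text else 0


def parse_hgvs_c(text: str) -> CodingVariant:
    """Parse an HGVS c. description into a :class:`CodingVariant`.

    Lossless over the supported subset: ``parse(format(v)) == v`` up to the
    raw string.  Accepts descriptions with or without "NM_..._"/"c."
    prefixes.
    """
    raw = text.strip()
    body = _PREFIX_RE.sub("", raw, count=1)
    if not body:
        raise HgvsParseError(f"empty HGVS description: {text!r}")
    for token in _UNSUPPORTED:
        if token in body:
            raise UnsupportedHgvsError(
                f"HGVS feature {token!r} in {text!r} is outside the supported subset"
            )

    m = _SUB_RE.match(body)
    if m:
        anchor, off, ref, alt = m.groups()
        if ref == alt:
            raise HgvsParseError(f"substitution with identical alleles: {text!r}")
        return CodingVariant(
            raw=raw, kind="substitution", start=int(anchor),
            start_offset=_parse_offset(off), ref=ref, alt=alt,
        )

    for regex, kind in ((_DELINS_RE, "delins"), (_DEL_RE, "deletion"), (_DUP_RE, "duplication")):
        m = regex.match(body)
        if m:
            s, soff, e, eoff, seq = m.groups()
            start, start_offset = int(s), _parse_offset(soff)
            end = int(e) if e else start
            end_offset = _parse_offset(eoff) if e else start_offset
            if (end, end_offset) < (start, start_offset):
                raise HgvsParseError(f"range start > end in {text!r}")
            ref = seq if kind != "delins" else ""
            alt = seq if kind == "delins" else ""
            if kind == "duplication":
                ref, alt = seq, ""
            return CodingVariant(
                raw=raw, kind=kind, start=start, start_offset=start_offset,
                end=end, end_offset=end_offset, ref=ref, alt=alt,
            )

    m = _INS_RE.match(body)
    if m:
        s, soff, e, eoff, seq = m.groups()
        start, end = int(s), int(e)
        start_offset, end_offset = _parse_offset(soff), _parse_offset(eoff)
        if (start_offset, end_offset) == (0, 0) and end != start + 1:
            raise HgvsParseError(
                f"insertion must sit between adjacent positions, got {text!r}"
            )
        return CodingVariant(
            raw=raw, kind="insertion", start=start, start_offset=start_offset,
            end=end, end_offset=end_offset, alt=seq,
        )

    raise HgvsParseError(f"cannot parse HGVS description {text!r} (offending part: {body!r})")


# -- reference checks and normalization ---------------------------------

def _check_exonic_span(v: CodingVariant, model: GeneModel) -> None:
    if v.is_intronic:
        raise CoordinateError(f"{v} is intronic; exonic operation requested")
    lo, hi = v.span
    if not (1 <= lo <= hi <= model.cds_length):
        raise CoordinateError(f"{v} outside the CDS (1..{model.cds_length})")


def check_reference(v: CodingVariant, model: GeneModel) -> None:
    """Hard error when a stated reference allele disagrees with the model.

    Silent mismatches would corrupt every downstream count, so this is never
    a warning.
    """
    if v.is_intronic or not v.ref:
        return
    lo, hi = v.span
    if v.kind == "substitution":
        actual = model.base(lo)
    else:
        actual = model.cds_sequence[lo - 1 : hi]
    if actual != v.ref:
        raise ReferenceMismatchError(
            f"{v}: stated reference {v.ref!r} but model has {actual!r} at c.{lo}"
        )


def normalize_indel(v: CodingVariant, model: GeneModel) -> CodingVariant:
    """3'-shift an exonic deletion/duplication/insertion per HGVS convention.

    Idempotent; insertions that duplicate the immediately preceding sequence
    are rewritten as duplications.  Substitutions and delins pass through
    unchanged.
    """
    if v.kind in ("substitution", "delins") or v.is_intronic:
        check_reference(v, model)
        return v
    _check_exonic_span(v, model)
    check_reference(v, model)
    cds = model.cds_sequence

    if v.kind in ("deletion", "duplication"):
        lo, hi = v.span
        unit_len = hi - lo + 1
        while hi < model.cds_length and cds[hi] == cds[lo - 1]:
            lo += 1
            hi += 1
        unit = cds[lo - 1 : hi]
        return replace(
            v, start=lo, end=hi if unit_len > 1 else None, end_offset=0,
            ref=unit if v.ref else "", raw=v.raw,
        )

    # insertion between start and end=start+1
    seq = v.alt
    pos = v.start  # insertion after cDNA position pos
    while pos < model.cds_length and cds[pos] == seq[0]:
        seq = seq[1:] + seq[0]
        pos += 1
    if pos >= len(seq) and cds[pos - len(seq) : pos] == seq:
        # equals the preceding sequence -> duplication of that unit
        lo = pos - len(seq) + 1
        return CodingVariant(
            raw=v.raw, kind="duplication", start=lo,
            end=pos if len(seq) > 1 else None, ref=seq,
        )
    return replace(v, start=pos, end=pos + 1, alt=seq)


# -- classification -----------------------------------------------------

@dataclass(frozen=True)
class VariantAnnotation:
    variant: CodingVariant
    var_class: str
    codon: int | None = None
    protein_hgvs: str | None = None
    event: str = "other"  # six substitution classes | "indel" | "other"
    cpg: bool | None = None
    splice_signal: SpliceSignal | None = None
    pathogenicity_label: str | None = None  # P | LP | VUS | LB | B
    certified_oncogenic: bool | None = None


def mutational_event(v: CodingVariant, model: GeneModel) -> tuple[str, bool | None]:
    """Collapse a substitution onto its strand-symmetric event class.

    Returns (event, cpg).  ``cpg`` is True for C>T at CpG or G>A at CpG
    (the deamination hotspot mechanism), None when the dinucleotide context
    is unknown (intronic position without sequence, or CDS edge).
    Indels return ("indel", None).
    """
    if v.kind != "substitution":
        return "indel", None
    event = _EVENT_OF[(v.ref, v.alt)]
    if v.is_intronic:
        return event, None
    if event != "GC>AT":
        return event, False
    pos = v.start
    if v.ref == "C":
        if pos >= model.cds_length:
            return event, None
        return event, model.base(pos + 1) == "G"
    # G>A: CpG when the preceding base is C
    if pos <= 1:
        return event, None
    return event, model.base(pos - 1) == "C"


def _protein_sub_name(model: GeneModel, codon: int, alt_aa: str) -> str:
    ref_aa = model.protein_sequence[codon - 1] if codon <= model.n_codons else "*"
    ref3 = "Ter" if ref_aa == "*" else seq3(ref_aa)
    if alt_aa == ref_aa:
        return f"p.{ref3}{codon}="
    if alt_aa == "*":
        return f"p.{ref3}{codon}Ter"
    if ref_aa == "*":
        return f"p.Ter{codon}{seq3(alt_aa)}ext*?"
    return f"p.{ref3}{codon}{seq3(alt_aa)}"


def classify_variant(
    v: CodingVariant,
    model: GeneModel,
    pathogenicity_label: str | None = None,
    certified_oncogenic: bool | None = None,
    protein_names: bool = True,
) -> VariantAnnotation:
    """Assign the variant class and per-variant annotations.

    Rules: intronic offset of magnitude 1 or 2 -> splice; other intronic ->
    intronic_other; exonic substitution -> missense/nonsense/synonymous by
    codon translation; exonic indel -> frameshift when the net length change
    is not a multiple of 3, else inframe_indel.
    """
    event, cpg = mutational_event(v, model)

    if v.is_intronic:
        offsets = {v.start_offset, v.end_offset} - {0}
        signal = None
        for anchor, off in ((v.start, v.start_offset), (v.end or v.start, v.end_offset)):
            if off != 0:
                signal = signal or signal_at(model, anchor, off)
        var_class = "splice" if any(abs(o) in (1, 2) for o in offsets) and signal else (
            "splice" if any(abs(o) in (1, 2) for o in offsets) else "intronic_other"
        )
        return VariantAnnotation(
            variant=v, var_class=var_class, event=event, cpg=cpg,
            splice_signal=signal, pathogenicity_label=pathogenicity_label,
            certified_oncogenic=certified_oncogenic,
        )

    _check_exonic_span(v, model)
    check_reference(v, model)

    if v.kind == "substitution":
        codon, pos_in_codon = cdna_to_codon(model, v.start)
        ref_codon = model.codon_sequence(codon)
        alt_codon = (
            ref_codon[: pos_in_codon - 1] + v.alt + ref_codon[pos_in_codon:]
        )
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if alt_aa == ref_aa:
            var_class = "synonymous"
        elif alt_aa == "*":
            var_class = "nonsense"
        else:
            var_class = "missense"  # includes the rare stop-loss edge (ext naming)
        name = _protein_sub_name(model, codon, alt_aa) if protein_names else None
        return VariantAnnotation(
            variant=v, var_class=var_class, codon=codon, protein_hgvs=name,
            event=event, cpg=cpg, pathogenicity_label=pathogenicity_label,
            certified_oncogenic=certified_oncogenic,
        )

    # exonic indel
    lo, hi = v.span
    if v.kind == "deletion":
        net = -(hi - lo + 1)
    elif v.kind == "duplication":
        net = hi - lo + 1
    elif v.kind == "insertion":
        net = len(v.alt)
    else:  # delins
        net = len(v.alt) - (hi - lo + 1)
    codon, _ = cdna_to_codon(model, lo if v.kind != "insertion" else min(hi, model.cds_length))
    var_class = "frameshift" if net % 3 != 0 else "inframe_indel"
    name = None
    if protein_names and var_class == "frameshift":
        from .consequence import translate_frameshift  # local import avoids a cycle

        name = translate_frameshift(v, model).protein_hgvs
    return VariantAnnotation(
        variant=v, var_class=var_class, codon=codon, protein_hgvs=name,
        event="indel", cpg=None, pathogenicity_label=pathogenicity_label,
        certified_oncogenic=certified_oncogenic,
    )
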