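"""Protein-level consequence prediction.

Three routes, all over the :class:`~tp53kit.reference.GeneModel` coding
sequence and the standard nuclear genetic code:

* frameshift translation with HGVS p. naming (``p.Arg209LysfsTer6`` style,
  Ter counted from the first changed residue);
* nonsense truncation (``p.Arg213Ter`` style);
* splice-acceptor disruption with cryptic-acceptor isoform construction:
  when the canonical -2/-1 acceptor AG of an intron is destroyed, splicing
  can shift to an upstream cryptic AG, retaining the intervening intronic
  3' segment in the mRNA.  For TP53 intron 6 the experimentally supported
  cryptic site sits 49 nt upstream of the canonical acceptor; its use
  retains 49 intronic nucleotides, shifts the exon-7 reading frame and
  terminates translation early in exon 7 — the architecture of the
  naturally occurring truncated isoform p53psi.

Products truncated in the exon-6/early-exon-7 window are tagged
``psi_like`` by that structural rule alone; no functional claim is made.
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .errors import CapabilityError, CoordinateError, Tp53KitError, UnsupportedHgvsError
from .hgvs import CodingVariant, check_reference
from .reference import GeneModel, SpliceSignal, signal_at

# default cryptic-acceptor offset for TP53 intron 6 (nt upstream of the
# canonical acceptor); the experimentally supported p53psi site
PSI_CRYPTIC_OFFSET = 49

# structural window for the psi_like tag: stop codon within exon 6 or the
# first 20 codons of exon 7 (where p53psi and the CLL truncating hotspots end)
_PSI_EXON = 6
_PSI_NEXT_EXON_CODONS = 20


@dataclass(frozen=True)
class ProteinConsequence:
    protein_hgvs: str
    product_sequence: str  # predicted product, no stop character
    novel_cterm: str  # residues after the last reference-matching prefix
    truncation_codon: int | None  # stop position in product numbering, or None
    isoform_tag: str  # full_length | truncated | psi_like
    no_stop: bool = False  # frame ran off the sequence end before a stop


@dataclass(frozen=True)
class SpliceOutcome:
    disrupted_signal: SpliceSignal
    cryptic_site_offset: int  # nt upstream of the canonical acceptor (= retained length)
    retained_sequence: str
    predicted_transcript: str
    consequence: ProteinConsequence


def apply_to_cds(v: CodingVariant, cds: str) -> str:
    """Return the coding sequence with the exonic variant applied."""
    if v.is_intronic:
        raise CoordinateError(f"{v} is intronic; cannot apply to the CDS")
    lo, hi = v.span
    if not (1 <= lo <= hi <= len(cds)):
        raise CoordinateError(f"{v} outside the CDS (1..{len(cds)})")
    if v.kind == "substitution":
        return cds[: lo - 1] + v.alt + cds[lo:]
    if v.kind == "deletion":
        return cds[: lo - 1] + cds[hi:]
    if v.kind == "duplication":
        return cds[: hi] + cds[lo - 1 : hi] + cds[hi:]
    if v.kind == "insertion":
        return cds[: lo] + v.alt + cds[lo:]
    if v.kind == "delins":
        return cds[: lo - 1] + v.alt + cds[hi:]
    raise ValueError(f"unknown variant kind {v.kind!r}")


def _translate_to_stop(nt: str) -> tuple[str, bool]:
    """Translate frame 1 until the first stop; returns (protein, stop_found)."""
    usable = nt[: len(nt) - len(nt) % 3]
    prot = str(Seq(usable).translate())
    if "*" in prot:
        return prot[: prot.index("*")], True
    return prot, False


def _codon_exon(model: GeneModel, codon: int) -> int:
    """Exon containing the first base of a codon."""
    return model.exon_of((codon - 1) * 3 + 1).number


def _psi_tag(model: GeneModel, truncation_codon: int | None) -> str:
    """truncated vs psi_like by the structural window rule."""
    if truncation_codon is None:
        return "truncated"
    try:
        psi_exon = next(e for e in model.exons if e.number == _PSI_EXON)
        next_exon = next(e for e in model.exons if e.number == _PSI_EXON + 1)
    except StopIteration:
        return "truncated"
    import math

    lo = math.ceil(psi_exon.start / 3)
    hi = math.ceil(next_exon.start / 3) + _PSI_NEXT_EXON_CODONS
    return "psi_like" if lo <= truncation_codon <= hi else "truncated"


def name_from_products(reference: str, product: str, no_stop: bool = False) -> str:
    """Derive the HGVS p. name by diffing a predicted product against the
    reference protein.  Used both to emit names and (re-applied to a
    consequence's own product) to check naming self-consistency."""
    i = 0
    limit = min(len(reference), len(product))
    while i < limit and reference[i] == product[i]:
        i += 1
    if i == len(product):
        if i == len(reference):
            return "p.="
        # product is a clean prefix: stop gained right after position i
        return f"p.{seq3(reference[i])}{i + 1}Ter"
    ref_aa = reference[i] if i < len(reference) else "*"
    ref3 = "Ter" if ref_aa == "*" else seq3(ref_aa)
    ter = "?" if no_stop else str(len(product) - i + 1)
    return f"p.{ref3}{i + 1}{seq3(product[i])}fsTer{ter}"


def translate_frameshift(v: CodingVariant, model: GeneModel) -> ProteinConsequence:
    """Translate a frame-shifting exonic indel and name it per HGVS.

    The edited CDS is translated from codon 1 to the first stop in the
    shifted frame; ``fsTer`` counts the stop from the first changed residue
    (that residue = 1).  When no stop is reached before the sequence end the
    name carries ``fsTer?`` and ``no_stop`` is set.
    """
    if v.kind == "substitution":
        raise Tp53KitError(f"{v} is a substitution, not an indel")
    lo, hi = v.span
    if v.kind == "deletion":
        net = -(hi - lo + 1)
    elif v.kind == "duplication":
        net = hi - lo + 1
    elif v.kind == "insertion":
        net = len(v.alt)
    else:
        net = len(v.alt) - (hi - lo + 1)
    if net % 3 == 0:
        raise Tp53KitError(f"{v} does not shift the reading frame (net {net:+d} nt)")
    check_reference(v, model)
    mutated = apply_to_cds(v, model.cds_sequence)
    product, stop_found = _translate_to_stop(mutated)
    reference = model.protein_sequence

    i = 0
    limit = min(len(reference), len(product))
    while i < limit and reference[i] == product[i]:
        i += 1
    novel = product[i:]
    if i == len(product) and stop_found:
        # immediate stop at the first changed codon
        return ProteinConsequence(
            protein_hgvs=f"p.{seq3(reference[i])}{i + 1}Ter",
            product_sequence=product,
            novel_cterm="",
            truncation_codon=i + 1,
            isoform_tag=_psi_tag(model, i + 1),
        )
    truncation = len(product) + 1 if stop_found else None
    name = name_from_products(reference, product, no_stop=not stop_found)
    return ProteinConsequence(
        protein_hgvs=name,
        product_sequence=product,
        novel_cterm=novel,
        truncation_codon=truncation,
        isoform_tag=_psi_tag(model, truncation) if stop_found else "truncated",
        no_stop=not stop_found,
    )


def translate_nonsense(v: CodingVariant, model: GeneModel) -> ProteinConsequence:
    """Truncation product of a stop-gain substitution."""
    if v.kind != "substitution" or v.is_intronic:
        raise Tp53KitError(f"{v} is not an exonic substitution")
    check_reference(v, model)
    mutated = apply_to_cds(v, model.cds_sequence)
    product, stop_found = _translate_to_stop(mutated)
    reference = model.protein_sequence
    if not stop_found or len(product) >= len(reference):
        raise Tp53KitError(
            f"{v} does not create a premature stop codon; classify it first"
        )
    codon = len(product) + 1
    return ProteinConsequence(
        protein_hgvs=f"p.{seq3(reference[codon - 1])}{codon}Ter",
        product_sequence=product,
        novel_cterm="",
        truncation_codon=codon,
        isoform_tag=_psi_tag(model, codon),
    )


def _find_acceptor_intron(v: CodingVariant, model: GeneModel):
    """(intron, signal) for a variant hitting an acceptor -1/-2 position."""
    if v.kind != "substitution" or v.start_offset not in (-1, -2):
        return None, None
    signal = signal_at(model, v.start, v.start_offset)
    if signal is None or signal.side != "acceptor":
        return None, None
    return model.intron(signal.intron_number), signal


def predict_splice_outcome(
    v: CodingVariant,
    model: GeneModel,
    cryptic_rule: str = "fixed_offset",
    fixed_offset: int = PSI_CRYPTIC_OFFSET,
) -> SpliceOutcome:
    """Model the transcript produced when an acceptor signal is disrupted.

    ``fixed_offset`` (default) places the cryptic acceptor a set number of
    nucleotides upstream of the canonical one — 49 for TP53 intron 6, the
    experimentally supported p53psi site.  ``scan`` instead picks the
    nearest upstream AG dinucleotide not itself destroyed by the variant
    (ties broken toward the canonical site), which suits synthetic genes.

    The predicted transcript keeps all exons and retains the intronic 3'
    segment downstream of the cryptic site; it is translated in full and
    tagged ``psi_like`` when the retention shifts the downstream frame into
    an early stop.
    """
    if v.kind == "substitution" and v.start_offset in (1, 2):
        raise UnsupportedHgvsError(
            f"{v} hits a donor signal; donor-site outcomes are out of scope"
        )
    intron, signal = _find_acceptor_intron(v, model)
    not_disrupting = intron is None
    if not_disrupting and cryptic_rule != "scan":
        raise Tp53KitError(
            f"{v} does not hit an acceptor -1/-2 position; "
            "use scan mode for the no-op control"
        )

    if cryptic_rule not in ("fixed_offset", "scan"):
        raise ValueError(f"unknown cryptic_rule {cryptic_rule!r}")

    if not_disrupting:
        # scan-mode control: canonical acceptor intact, wild-type product
        reference = model.protein_sequence
        return SpliceOutcome(
            disrupted_signal=None,
            cryptic_site_offset=0,
            retained_sequence="",
            predicted_transcript=model.cds_sequence,
            consequence=ProteinConsequence(
                protein_hgvs="p.=",
                product_sequence=reference,
                novel_cterm="",
                truncation_codon=None,
                isoform_tag="full_length",
            ),
        )

    intron_seq = model.intron_sequence(intron.number)  # CapabilityError when absent

    # apply the variant to the intron 3' end: offset -1 is the last intron
    # base, -2 the one before
    pos_from_end = -v.start_offset  # 1 or 2
    idx = len(intron_seq) - pos_from_end
    if intron_seq[idx] != v.ref:
        raise Tp53KitError(
            f"{v}: intron {intron.number} sequence has {intron_seq[idx]!r} at "
            f"position {v.start_offset}, not {v.ref!r}"
        )
    mutated_intron = intron_seq[:idx] + v.alt + intron_seq[idx + 1 :]

    if cryptic_rule == "fixed_offset":
        retained_len = fixed_offset
        if retained_len + 2 > len(intron_seq):
            raise CapabilityError(
                f"intron {intron.number} shorter than the fixed cryptic offset"
            )
        cryptic = mutated_intron[-(retained_len + 2) : -retained_len]
        if cryptic != "AG":
            raise Tp53KitError(
                f"no AG acceptor dinucleotide {retained_len} nt upstream of the "
                f"canonical acceptor of intron {intron.number}"
            )
    else:
        # nearest upstream AG whose dinucleotide survives the variant;
        # canonical itself (retained 0) wins when intact
        retained_len = None
        for cand in range(0, len(mutated_intron) - 1):
            end = len(mutated_intron) - cand  # AG occupies [end-2, end)
            if mutated_intron[end - 2 : end] == "AG":
                retained_len = cand
                break
        if retained_len is None:
            raise CapabilityError(
                f"no surviving AG acceptor found in intron {intron.number}"
            )

    retained = mutated_intron[len(mutated_intron) - retained_len :]
    boundary = intron.acceptor_anchor - 1  # 0-based index of the downstream exon start
    transcript = model.cds_sequence[:boundary] + retained + model.cds_sequence[boundary:]
    product, stop_found = _translate_to_stop(transcript)
    reference = model.protein_sequence

    i = 0
    limit = min(len(reference), len(product))
    while i < limit and reference[i] == product[i]:
        i += 1
    novel = product[i:]
    truncation = len(product) + 1 if stop_found else None
    if retained_len == 0:
        name, tag = "p.=", "full_length"
    elif stop_found and len(product) < len(reference):
        # psi_like: frame shifted by the retention and stop reached within
        # the retained segment + early downstream exon window
        stop_nt = len(product) * 3  # 0-based nt index where the stop codon starts
        early = stop_nt <= boundary + retained_len + 3 * _PSI_NEXT_EXON_CODONS
        tag = "psi_like" if retained_len % 3 != 0 and early else "truncated"
        name = name_from_products(reference, product)
    else:
        tag = "truncated"
        name = name_from_products(reference, product, no_stop=not stop_found)
    consequence = ProteinConsequence(
        protein_hgvs=name,
        product_sequence=product,
        novel_cterm=novel,
        truncation_codon=truncation,
        isoform_tag=tag,
        no_stop=not stop_found,
    )
    return SpliceOutcome(
        disrupted_signal=signal,
        cryptic_site_offset=retained_len,
        retained_sequence=retained,
        predicted_transcript=transcript,
        consequence=consequence,
    )
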