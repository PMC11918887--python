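"""Gene model: transcript coordinate system, sequences and splice signals.

Everything downstream works in HGVS cDNA coordinates (1-based, inclusive;
position 1 is the A of the start codon; intronic positions are written
anchor+offset / anchor-offset relative to the nearest exonic base).
Genomic coordinates are never exposed.

The packaged TP53 model (``tp53_model()``) covers the major transcript
NM_000546 / protein NP_000537: a 1,182-nt CDS encoding the 393-residue
full-length p53, distributed over ten coding exons (numbered 2-11, as in
the gene; exon 1 is noncoding).  The gene has ten introns and hence twenty
canonical splice signals; intron 1 flanks the noncoding exon 1, so its two
signals carry no cDNA-addressable coordinates here.  Only the intron 6
sequence ships with the package (a synthetic stand-in reproducing the
3'-end architecture needed for cryptic-acceptor prediction); the other
intron sequences are absent and splice-consequence prediction degrades
gracefully for them.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import CapabilityError, CoordinateError, Tp53KitError

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Exon:
    number: int
    start: int  # cDNA, 1-based inclusive
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SpliceSignal:
    """One canonical splice signal: the +1/+2 donor or -2/-1 acceptor
    dinucleotide of an intron, addressed by HGVS intronic coordinates."""

    intron_number: int
    side: str  # "donor" | "acceptor"
    anchor: int | None  # exonic cDNA position the offsets hang off
    positions: tuple[str, str] | None  # e.g. ("673-2", "673-1"); None if not cDNA-addressable

    @property
    def cdna_addressable(self) -> bool:
        return self.positions is not None

    def covers(self, anchor: int, offset: int) -> bool:
        if self.anchor is None:
            return False
        if self.side == "donor":
            return anchor == self.anchor and offset in (1, 2)
        return anchor == self.anchor and offset in (-1, -2)


@dataclass(frozen=True)
class Intron:
    number: int
    donor_anchor: int | None  # last cDNA base of the upstream exon
    acceptor_anchor: int | None  # first cDNA base of the downstream exon
    sequence: str | None = None  # genomic intron sequence, 5'->3', or absent


@dataclass(frozen=True)
class InvertedRepeat:
    left_start: int  # cDNA position of the first base of the left arm
    arm: str  # left-arm sequence; the right arm is its reverse complement
    spacer: int  # bases between the arms

    @property
    def right_start(self) -> int:
        return self.left_start + len(self.arm) + self.spacer


@dataclass(frozen=True)
class GeneModel:
    transcript_id: str
    protein_id: str
    cds_sequence: str
    exons: tuple[Exon, ...]
    introns: tuple[Intron, ...]
    strand: str = "+"
    protein_sequence: str = field(init=False)

    def __post_init__(self) -> None:
        prot = str(Seq(self.cds_sequence).translate())
        object.__setattr__(self, "protein_sequence", prot[:-1])

    # -- basic geometry -------------------------------------------------
    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3 - 1  # excludes the stop codon

    def exon_of(self, pos: int) -> Exon:
        for exon in self.exons:
            if exon.start <= pos <= exon.end:
                return exon
        raise CoordinateError(f"cDNA position {pos} outside the CDS (1..{self.cds_length})")

    def base(self, pos: int) -> str:
        if not 1 <= pos <= self.cds_length:
            raise CoordinateError(f"cDNA position {pos} outside the CDS (1..{self.cds_length})")
        return self.cds_sequence[pos - 1]

    def codon_sequence(self, codon_number: int) -> str:
        if not 1 <= codon_number <= self.cds_length // 3:
            raise CoordinateError(f"codon {codon_number} outside 1..{self.cds_length // 3}")
        return self.cds_sequence[(codon_number - 1) * 3 : codon_number * 3]

    def intron(self, number: int) -> Intron:
        for intron in self.introns:
            if intron.number == number:
                return intron
        raise CoordinateError(f"model has no intron {number}")

    def intron_sequence(self, number: int) -> str:
        seq = self.intron(number).sequence
        if seq is None:
            raise CapabilityError(
                f"intron {number} sequence is not available in this gene model; "
                "splice-consequence prediction needs it"
            )
        return seq


def cdna_to_codon(model: GeneModel, pos: int) -> tuple[int, int]:
    """Map an exonic cDNA position to (codon_number, position_in_codon).

    Intronic coordinates are rejected here; route them through the splice
    machinery instead.
    """
    if not 1 <= pos <= model.cds_length:
        raise CoordinateError(f"cDNA position {pos} outside the CDS (1..{model.cds_length})")
    return math.ceil(pos / 3), (pos - 1) % 3 + 1


def splice_signal_catalogue(model: GeneModel) -> list[SpliceSignal]:
    """The two canonical signals (donor +1/+2, acceptor -2/-1) of every intron."""
    if not model.introns:
        raise CapabilityError("gene model has no introns")
    signals: list[SpliceSignal] = []
    for intron in model.introns:
        if intron.donor_anchor is None:
            signals.append(SpliceSignal(intron.number, "donor", None, None))
        else:
            a = intron.donor_anchor
            signals.append(SpliceSignal(intron.number, "donor", a, (f"{a}+1", f"{a}+2")))
        if intron.acceptor_anchor is None:
            signals.append(SpliceSignal(intron.number, "acceptor", None, None))
        else:
            a = intron.acceptor_anchor
            signals.append(SpliceSignal(intron.number, "acceptor", a, (f"{a}-2", f"{a}-1")))
    return signals


def signal_at(model: GeneModel, anchor: int, offset: int) -> SpliceSignal | None:
    """Signal covering an intronic HGVS coordinate, e.g. (673, -2) -> intron 6
    acceptor; None when the coordinate is deeper intronic."""
    for signal in splice_signal_catalogue(model):
        if signal.covers(anchor, offset):
            return signal
    return None


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def inverted_repeat_context(
    model: GeneModel,
    cdna_range: tuple[int, int],
    arm_len: int = 4,
    max_spacer: int = 4,
) -> list[InvertedRepeat]:
    """Inverted repeats (arm + spacer + reverse-complement arm) whose window
    intersects ``cdna_range``.

    Such quasi-palindromes can extrude hairpins during replication and are a
    recognised source of small insertions/deletions; the TP53 region around
    codons 209-210 carries one (GAAA..4nt..TTTC) that rationalises the
    c.626_627del hotspot.
    """
    lo, hi = cdna_range
    if arm_len < 3:
        raise ValueError("arm_len must be >= 3")
    if not (1 <= lo <= hi <= model.cds_length):
        raise CoordinateError(f"range {cdna_range} outside the CDS (1..{model.cds_length})")
    seq = model.cds_sequence
    hits: list[InvertedRepeat] = []
    for left_start in range(1, model.cds_length - 2 * arm_len + 2):
        left = seq[left_start - 1 : left_start - 1 + arm_len]
        for spacer in range(0, max_spacer + 1):
            right_start = left_start + arm_len + spacer
            right = seq[right_start - 1 : right_start - 1 + arm_len]
            if len(right) < arm_len:
                break
            if right == _revcomp(left):
                window_lo, window_hi = left_start, right_start + arm_len - 1
                if window_lo <= hi and window_hi >= lo:
                    hits.append(InvertedRepeat(left_start, left, spacer))
    return hits


# -- construction -------------------------------------------------------

def _validate(model: GeneModel) -> GeneModel:
    cds = model.cds_sequence
    if len(cds) % 3 != 0:
        raise Tp53KitError(f"CDS length {len(cds)} is not a multiple of 3")
    if set(cds) - set("ACGT"):
        raise Tp53KitError("CDS contains non-ACGT characters")
    if cds[:3] != "ATG":
        raise Tp53KitError("CDS does not start with ATG")
    if cds[-3:] not in STOP_CODONS:
        raise Tp53KitError("CDS does not end with a stop codon")
    prot = str(Seq(cds).translate())
    if "*" in prot[:-1]:
        raise Tp53KitError("CDS contains an internal stop codon")
    expect = 1
    for exon in model.exons:
        if exon.start != expect:
            raise Tp53KitError(
                f"exon table gap/overlap: exon {exon.number} starts at {exon.start}, expected {expect}"
            )
        if exon.end < exon.start:
            raise Tp53KitError(f"exon {exon.number} has end < start")
        expect = exon.end + 1
    if expect - 1 != len(cds):
        raise Tp53KitError(
            f"exon table spans {expect - 1} nt but the CDS is {len(cds)} nt"
        )
    return model


def build_gene_model(
    transcript_id: str,
    protein_id: str,
    cds_sequence: str,
    exon_table: list[tuple[int, int, int]],
    intron_sequences: dict[int, str] | None = None,
    upstream_noncoding_intron: bool = False,
    strand: str = "+",
) -> GeneModel:
    """Assemble and validate a GeneModel from in-memory pieces.

    ``exon_table`` lists (exon_number, cdna_start, cdna_end) for the coding
    exons in order.  ``upstream_noncoding_intron`` adds one intron upstream
    of the first coding exon (for genes whose first exon is noncoding, like
    TP53); that intron's signals are not cDNA-addressable.
    """
    intron_sequences = intron_sequences or {}
    exons = tuple(Exon(n, s, e) for n, s, e in exon_table)
    introns: list[Intron] = []
    if upstream_noncoding_intron:
        first = exons[0].number - 1
        introns.append(Intron(first, None, None, intron_sequences.get(first)))
    for left, right in zip(exons, exons[1:]):
        number = left.number
        introns.append(
            Intron(number, left.end, right.start, intron_sequences.get(number))
        )
    model = GeneModel(
        transcript_id=transcript_id,
        protein_id=protein_id,
        cds_sequence=cds_sequence.upper(),
        exons=exons,
        introns=tuple(introns),
        strand=strand,
    )
    return _validate(model)


def _read_single_fasta(path: Path | str) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise Tp53KitError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    return str(records[0].seq).upper()


def _read_exon_table(path: Path | str) -> list[tuple[int, int, int]]:
    rows: list[tuple[int, int, int]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        need = {"exon_number", "cdna_start", "cdna_end"}
        if not need <= set(header):
            raise Tp53KitError(f"{path}: exon table needs columns {sorted(need)}")
        idx = {name: header.index(name) for name in need}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append(
                (
                    int(parts[idx["exon_number"]]),
                    int(parts[idx["cdna_start"]]),
                    int(parts[idx["cdna_end"]]),
                )
            )
    return rows


def load_gene_model(
    transcript_fasta: Path | str,
    exon_table: Path | str,
    intron_fastas: dict[int, Path | str] | None = None,
    transcript_id: str = "NM_000546",
    protein_id: str = "NP_000537",
    upstream_noncoding_intron: bool = False,
) -> GeneModel:
    """Load a validated GeneModel from FASTA + exon-table files.

    The transcript FASTA must contain the CDS only (position 1 = A of ATG).
    ``intron_fastas`` maps intron number to a FASTA with that intron's
    genomic sequence; introns without a file are marked sequence-absent.
    """
    cds = _read_single_fasta(transcript_fasta)
    exons = _read_exon_table(exon_table)
    introns = {
        number: _read_single_fasta(path)
        for number, path in (intron_fastas or {}).items()
    }
    return build_gene_model(
        transcript_id,
        protein_id,
        cds,
        exons,
        intron_sequences=introns,
        upstream_noncoding_intron=upstream_noncoding_intron,
    )


_TP53_CACHE: GeneModel | None = None


def tp53_model() -> GeneModel:
    """The packaged TP53 (NM_000546 / NP_000537) gene model.

    CDS and exon boundaries are the canonical coding-exon table of the major
    transcript; the intron 6 sequence is a synthetic stand-in reproducing
    the 3'-end architecture (canonical acceptor AG, cryptic acceptor AG 49 nt
    upstream, no intervening AG) required for psi-isoform prediction — see
    the data file headers.
    """
    global _TP53_CACHE
    if _TP53_CACHE is None:
        data = resources.files("tp53kit") / "data"
        _TP53_CACHE = load_gene_model(
            str(data / "tp53_cds.fasta"),
            str(data / "tp53_exons.tsv"),
            intron_fastas={6: str(data / "tp53_intron6_synthetic.fasta")},
            upstream_noncoding_intron=True,
        )
    return _TP53_CACHE
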