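"""Read-backed cis/trans phasing and long-read allele reconstruction.

Short-read phasing examines reads that span two variant positions in the
same exon no more than a configurable distance apart (default 50 nt) and
classifies the pair as cis (both variants on the same molecule), trans
(on different molecules) or ambiguous.  The "absent" haplotype count is
compared against a binomial upper bound at the stated per-site error
rate, so a handful of chimeric/error reads does not flip a call.

Long-read (SMRT-style) reconstruction groups reads spanning *all* variant
positions by their full variant-combination signature and reports allele
frequencies, including the wild-type allele.

Reads come either from a SAM file (standard flags honored; the reference
contig is the spliced coding sequence, i.e. amplicon coordinates equal
cDNA coordinates) or from a simplified TSV of per-read calls
(columns: read_id, then one column per variant with values ref/alt/uncalled).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam
from scipy import stats

from .errors import Tp53KitError
from .hgvs import CodingVariant, format_hgvs_c
from .reference import GeneModel

DEFAULT_MIN_SUPPORT = 20
DEFAULT_ERROR_RATE = 0.005
ERROR_BOUND_QUANTILE = 0.999


@dataclass(frozen=True)
class ReadObservation:
    read_id: str
    allele_calls: dict  # canonical hgvs string -> "ref" | "alt" | "uncalled"

    def call(self, variant: CodingVariant | str) -> str:
        key = variant if isinstance(variant, str) else format_hgvs_c(variant)
        return self.allele_calls.get(key, "uncalled")


@dataclass(frozen=True)
class PhaseCall:
    pair: tuple[str, str]
    n_ref_ref: int
    n_alt_ref: int
    n_ref_alt: int
    n_alt_alt: int
    configuration: str  # cis | trans | ambiguous
    reason: str
    min_support: int
    error_rate: float
    error_bound: int

    @property
    def n_doubly_called(self) -> int:
        return self.n_ref_ref + self.n_alt_ref + self.n_ref_alt + self.n_alt_alt


@dataclass(frozen=True)
class AlleleTable:
    alleles: list  # of (signature tuple of alt-carrying hgvs strings, count, frequency)
    n_spanning_reads: int
    n_dropped_reads: int
    noise_floor: float

    def frequency(self, signature: tuple[str, ...]) -> float:
        for sig, _, freq in self.alleles:
            if sig == signature:
                return freq
        return 0.0

    @property
    def flagged(self) -> list:
        """Signatures below the noise floor (possible chimeras/errors)."""
        return [sig for sig, _, freq in self.alleles if freq < self.noise_floor]


def pair_eligibility(
    v1: CodingVariant, v2: CodingVariant, model: GeneModel, max_dist: int = 50
) -> bool:
    """True iff both variants are exonic, in the same exon, and no more than
    ``max_dist`` nt apart (inclusive bound)."""
    if v1.is_intronic or v2.is_intronic:
        return False
    e1, e2 = model.exon_of(v1.start).number, model.exon_of(v2.start).number
    if e1 != e2:
        return False
    lo1, hi1 = v1.span
    lo2, hi2 = v2.span
    return abs(lo2 - lo1) <= max_dist and abs(hi2 - hi1) <= max_dist


# -- read ingestion -----------------------------------------------------

def read_observations_from_tsv(path: Path | str) -> list[ReadObservation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "read_id" not in df.columns:
        raise Tp53KitError("read TSV needs a read_id column")
    variant_columns = [c for c in df.columns if c != "read_id"]
    observations = []
    for record in df.to_dict("records"):
        calls = {}
        for column in variant_columns:
            value = str(record[column])
            calls[column] = value if value in ("ref", "alt") else "uncalled"
        observations.append(ReadObservation(str(record["read_id"]), calls))
    return observations


def _call_substitution(aligned, ref_pos0: int, ref: str, alt: str) -> str:
    base = aligned.get(ref_pos0)
    if base is None:
        return "uncalled"
    if base == alt:
        return "alt"
    if base == ref:
        return "ref"
    return "uncalled"


def _call_in_read(read: pysam.AlignedSegment, v: CodingVariant) -> str:
    """Call ref/alt/uncalled for one variant in one aligned read.

    Substitutions are matched by the exact base aligned to the position;
    deletions by the absence of query bases over the deleted span with
    aligned flanks; duplications/insertions by an insertion of the right
    length at the expected point.  Soft-clipped/unaligned positions are
    uncalled.
    """
    pairs = read.get_aligned_pairs(matches_only=False)
    seq = read.query_sequence or ""
    by_ref = {rp: (qp, seq[qp] if qp is not None else None) for qp, rp in pairs if rp is not None}
    insertions: dict[int, int] = {}
    last_ref = None
    for qp, rp in pairs:
        if rp is not None:
            last_ref = rp
        elif qp is not None and last_ref is not None:
            insertions[last_ref] = insertions.get(last_ref, 0) + 1

    lo, hi = v.span
    lo0, hi0 = lo - 1, hi - 1
    if not (read.reference_start <= lo0 and hi0 < read.reference_end):
        return "uncalled"

    if v.kind == "substitution":
        entry = by_ref.get(lo0)
        if entry is None or entry[0] is None:
            return "uncalled"
        return _call_substitution({lo0: entry[1]}, lo0, v.ref, v.alt)

    if v.kind == "deletion":
        span = [by_ref.get(p) for p in range(lo0, hi0 + 1)]
        flank_left = by_ref.get(lo0 - 1)
        flank_right = by_ref.get(hi0 + 1)
        if flank_left is None or flank_right is None:
            return "uncalled"
        if flank_left[0] is None or flank_right[0] is None:
            return "uncalled"
        deleted = all(e is not None and e[0] is None for e in span)
        present = all(e is not None and e[0] is not None for e in span)
        if deleted:
            return "alt"
        if present:
            return "ref"
        return "uncalled"

    if v.kind in ("insertion", "duplication"):
        # inserted sequence appears after the anchor (insertion) or after
        # the duplicated unit (duplication)
        if v.kind == "insertion":
            point, length = lo0, len(v.alt)
        else:
            point, length = hi0, hi - lo + 1
        entry = by_ref.get(point)
        if entry is None or entry[0] is None:
            return "uncalled"
        return "alt" if insertions.get(point, 0) == length else "ref"

    return "uncalled"


def read_observations_from_sam(
    path: Path | str, variants: list[CodingVariant]
) -> list[ReadObservation]:
    """Extract per-variant calls from a SAM file.

    Unmapped, secondary, supplementary and duplicate alignments are
    skipped.  The reference contig must use cDNA coordinates (the spliced
    CDS as reference), matching the simulator's SAM output.
    """
    observations = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            calls = {
                format_hgvs_c(v): _call_in_read(read, v) for v in variants
            }
            observations.append(ReadObservation(read.query_name, calls))
    return observations


def _as_observations(reads, variants) -> list[ReadObservation]:
    if isinstance(reads, (str, Path)):
        path = str(reads)
        if path.endswith(".sam"):
            return read_observations_from_sam(path, variants)
        return read_observations_from_tsv(path)
    return list(reads)


# -- phasing ------------------------------------------------------------

def error_consistent_bound(n: int, error_rate: float) -> int:
    """Largest count of the "absent" haplotype still consistent with the
    per-site error rate: the 99.9% binomial quantile at n trials."""
    if error_rate <= 0:
        return 0
    return int(stats.binom.ppf(ERROR_BOUND_QUANTILE, n, error_rate))


def phase_pair(
    reads,
    v1: CodingVariant,
    v2: CodingVariant,
    min_support: int = DEFAULT_MIN_SUPPORT,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> PhaseCall:
    """Classify a variant pair as cis / trans / ambiguous from reads.

    Only doubly-called reads count.  cis requires ``min_support`` alt/alt
    reads with both single-alt counts within the error bound; trans
    requires ``min_support`` reads for each single-alt haplotype with
    alt/alt within the error bound.  Everything else — insufficient
    coverage included — is ambiguous with a reason, never an error.
    """
    observations = _as_observations(reads, [v1, v2])
    k1, k2 = format_hgvs_c(v1), format_hgvs_c(v2)
    counts = {("ref", "ref"): 0, ("alt", "ref"): 0, ("ref", "alt"): 0, ("alt", "alt"): 0}
    for obs in observations:
        c1, c2 = obs.call(k1), obs.call(k2)
        if c1 == "uncalled" or c2 == "uncalled":
            continue
        counts[(c1, c2)] += 1
    n = sum(counts.values())
    bound = error_consistent_bound(n, error_rate)
    n_alt_ref = counts[("alt", "ref")]
    n_ref_alt = counts[("ref", "alt")]
    n_alt_alt = counts[("alt", "alt")]

    def build(configuration: str, reason: str) -> PhaseCall:
        return PhaseCall(
            pair=(k1, k2),
            n_ref_ref=counts[("ref", "ref")],
            n_alt_ref=n_alt_ref,
            n_ref_alt=n_ref_alt,
            n_alt_alt=n_alt_alt,
            configuration=configuration,
            reason=reason,
            min_support=min_support,
            error_rate=error_rate,
            error_bound=bound,
        )

    if n < min_support:
        return build("ambiguous", f"only {n} doubly-called reads (< {min_support})")
    cis_ok = n_alt_alt >= min_support and n_alt_ref <= bound and n_ref_alt <= bound
    trans_ok = (
        n_alt_ref >= min_support and n_ref_alt >= min_support and n_alt_alt <= bound
    )
    if cis_ok and trans_ok:
        return build("ambiguous", "cis and trans criteria both satisfied")
    if cis_ok:
        return build("cis", "alt/alt haplotype supported; single-alt within error bound")
    if trans_ok:
        return build("trans", "both single-alt haplotypes supported; alt/alt within error bound")
    return build("ambiguous", "no configuration meets the support thresholds")


def reconstruct_alleles(
    reads,
    variants: list[CodingVariant],
    noise_floor: float = 0.01,
) -> AlleleTable:
    """Group long reads by their full variant-combination signature.

    Reads not confidently called at every variant position are dropped
    (and counted); the wild-type allele is the empty signature.
    Signatures below ``noise_floor`` are flagged as possible chimeras or
    residual errors rather than removed.
    """
    observations = _as_observations(reads, variants)
    keys = [format_hgvs_c(v) for v in variants]
    signature_counts: dict[tuple[str, ...], int] = {}
    dropped = 0
    for obs in observations:
        calls = [obs.call(k) for k in keys]
        if "uncalled" in calls:
            dropped += 1
            continue
        signature = tuple(k for k, c in zip(keys, calls) if c == "alt")
        signature_counts[signature] = signature_counts.get(signature, 0) + 1
    n = sum(signature_counts.values())
    if n == 0:
        raise Tp53KitError("no reads span all variant positions")
    alleles = [
        (sig, count, count / n)
        for sig, count in sorted(
            signature_counts.items(), key=lambda kv: (-kv[1], kv[0])
        )
    ]
    return AlleleTable(alleles, n, dropped, noise_floor)
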