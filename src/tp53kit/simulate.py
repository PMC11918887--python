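"""Synthetic cohorts, reads and SNP profiles with the statistical structure
the analysis assumes.

The generator's defaults encode the study conditions the pipeline was
built for: a CLL-like cohort in which 73/11/2/6/8 percent of variants are
missense/frameshift/inframe/nonsense/splice, single/double/triple/4+
-mutated NGS patients occur at 69/16/8/7 percent, the codon-209 dinucleotide
deletion carries 16% of the frameshift weight, the three intron-6 acceptor
substitutions jointly carry 22% of the splice weight (split equally), the
substitution spectrum is transition-heavy with roughly one AT>GC event in
five, and roughly one patient in four is assayed by Sanger (no VAF).

The clone model is explicit: a patient is a mixture of subclones whose
cell fractions sum to at most 1 (wild-type residual makes up the rest);
each subclone carries its variants on one of two alleles.  A heterozygous
variant in a clone of fraction f has VAF = f/2 under diploidy, and VAF =
f under CN-LOH or del(17p).  Cumulated VAF per patient therefore never
exceeds 100% by construction.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; truth objects record every clone and phase
assignment.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .cnloh import SNPProfile
from .errors import Tp53KitError
from .hgvs import parse_hgvs_c
from .phasing import ReadObservation
from .reference import GeneModel, tp53_model

# catalogue-construction seed: fixes the identity of the menu's background
# variants; per-run randomness never flows through it
_MENU_SEED = 20230509

DEFAULT_CLASS_WEIGHTS = {
    "missense": 0.73,
    "frameshift": 0.11,
    "inframe_indel": 0.02,
    "nonsense": 0.06,
    "splice": 0.08,
}
DEFAULT_MULTICLONALITY_WEIGHTS = (0.69, 0.16, 0.08, 0.07)  # SM, DM, MM3, MM4plus
# background (non-hotspot) substitution event mixture; transition-heavy
DEFAULT_EVENT_MIX = {
    "GC>AT": 0.25, "AT>GC": 0.25, "GC>TA": 0.13, "GC>CG": 0.12,
    "AT>TA": 0.13, "AT>CG": 0.12,
}
SANGER_REGION = (97, 919)  # cDNA span screened by Sanger (exons 4-8)

_EVENT_ALTS = {
    "C": {"T": "GC>AT", "A": "GC>TA", "G": "GC>CG"},
    "G": {"A": "GC>AT", "T": "GC>TA", "C": "GC>CG"},
    "T": {"C": "AT>GC", "A": "AT>TA", "G": "AT>CG"},
    "A": {"G": "AT>GC", "T": "AT>TA", "C": "AT>CG"},
}


@dataclass(frozen=True)
class MenuEntry:
    hgvs: str
    var_class: str
    weight: float


@dataclass(frozen=True)
class Clone:
    fraction: float  # percent of cells
    variants: tuple  # hgvs strings
    phase: dict  # hgvs -> "A" | "B"


@dataclass(frozen=True)
class ClonalArchitecture:
    patient_id: str
    clones: tuple  # of Clone
    germline_het_snps: tuple = ()
    cnloh: bool = False
    del17p: bool = False
    # cell fraction (percent) carrying the CN-LOH/deletion event itself;
    # None -> the variant clones' summed fraction.  Full SNP homozygosity
    # requires the event to be near-clonal even when the TP53 variant is
    # subclonal within it.
    loh_fraction: float | None = None

    def __post_init__(self):
        total = sum(c.fraction for c in self.clones)
        if total > 100.0 + 1e-9:
            raise Tp53KitError(
                f"{self.patient_id}: clone fractions sum to {total:.1f}% (> 100)"
            )

    @property
    def wildtype_fraction(self) -> float:
        return 100.0 - sum(c.fraction for c in self.clones)


# -- variant menu -------------------------------------------------------

def _substitution_at(model: GeneModel, pos: int, event: str, rng) -> str | None:
    ref = model.base(pos)
    alts = [a for a, e in _EVENT_ALTS[ref].items() if e == event]
    if not alts:
        return None
    return f"c.{pos}{ref}>{alts[0]}"


def _classify_quick(model: GeneModel, pos: int, alt: str) -> str:
    codon = (pos - 1) // 3
    within = (pos - 1) % 3
    ref_codon = model.codon_sequence(codon + 1)
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    return "missense"


def default_variant_menu(
    model: GeneModel | None = None,
    class_weights: dict | None = None,
    event_mix: dict | None = None,
    n_background: int = 60,
) -> list[MenuEntry]:
    """The weighted variant catalogue cohorts are drawn from.

    Named hotspots carry their CLL shares; the background is a fixed,
    deterministically chosen set of substitutions matching ``event_mix``
    plus scattered frameshift/inframe indels.
    """
    model = model or tp53_model()
    class_weights = class_weights or DEFAULT_CLASS_WEIGHTS
    event_mix = event_mix or DEFAULT_EVENT_MIX
    rng = np.random.default_rng(_MENU_SEED)
    menu: list[MenuEntry] = []

    # --- missense: codon-234 hotspot + classical CpG hotspots + background
    w_mis = class_weights["missense"]
    hotspots = [
        ("c.700T>C", 0.05),   # p.Tyr234His, alkylating-treatment hotspot
        ("c.701A>G", 0.015),  # p.Tyr234Cys
        ("c.524G>A", 0.06),   # p.Arg175His (CpG)
        ("c.743G>A", 0.055),  # p.Arg248Gln (CpG)
        ("c.742C>T", 0.05),   # p.Arg248Trp (CpG)
        ("c.818G>A", 0.05),   # p.Arg273His (CpG)
        ("c.817C>T", 0.05),   # p.Arg273Cys (CpG)
        ("c.844C>T", 0.03),   # p.Arg282Trp (CpG)
    ]
    for hgvs, share in hotspots:
        menu.append(MenuEntry(hgvs, "missense", w_mis * share))
    remainder = 1.0 - sum(share for _, share in hotspots)
    events = list(event_mix)
    probs = np.array([event_mix[e] for e in events], dtype=float)
    probs /= probs.sum()
    background: list[str] = []
    taken = {h for h, _ in hotspots}
    attempts = 0
    while len(background) < n_background and attempts < 50 * n_background:
        attempts += 1
        pos = int(rng.integers(1, model.n_codons * 3 + 1))
        event = events[int(rng.choice(len(events), p=probs))]
        hgvs = _substitution_at(model, pos, event, rng)
        if hgvs is None or hgvs in taken:
            continue
        alt = hgvs[-1]
        if _classify_quick(model, pos, alt) != "missense":
            continue
        taken.add(hgvs)
        background.append(hgvs)
    for hgvs in background:
        menu.append(MenuEntry(hgvs, "missense", w_mis * remainder / len(background)))

    # --- nonsense: the two CLL-relevant truncating hotspots + background
    w_non = class_weights["nonsense"]
    menu.append(MenuEntry("c.637C>T", "nonsense", w_non * 0.35))  # p.Arg213Ter (CpG)
    menu.append(MenuEntry("c.586C>T", "nonsense", w_non * 0.25))  # p.Arg196Ter (CpG)
    stop_background: list[str] = []
    attempts = 0
    while len(stop_background) < 8 and attempts < 4000:
        attempts += 1
        pos = int(rng.integers(1, model.n_codons * 3 + 1))
        ref = model.base(pos)
        for alt in "ACGT".replace(ref, ""):
            hgvs = f"c.{pos}{ref}>{alt}"
            if hgvs not in taken and _classify_quick(model, pos, alt) == "nonsense":
                taken.add(hgvs)
                stop_background.append(hgvs)
                break
    for hgvs in stop_background:
        menu.append(MenuEntry(hgvs, "nonsense", w_non * 0.40 / len(stop_background)))

    # --- frameshift: codon-209 dinucleotide deletion at 16% + background
    w_fs = class_weights["frameshift"]
    menu.append(MenuEntry("c.626_627del", "frameshift", w_fs * 0.16))
    menu.append(MenuEntry("c.628del", "frameshift", w_fs * 0.04))  # codon-210 region
    fs_background: list[str] = []
    while len(fs_background) < 20:
        pos = int(rng.integers(10, model.n_codons * 3 - 10))
        width = int(rng.choice([1, 1, 2]))
        hgvs = f"c.{pos}del" if width == 1 else f"c.{pos}_{pos + 1}del"
        if hgvs not in taken:
            taken.add(hgvs)
            fs_background.append(hgvs)
    for hgvs in fs_background:
        menu.append(MenuEntry(hgvs, "frameshift", w_fs * 0.80 / len(fs_background)))

    # --- inframe: scattered codon deletions
    w_if = class_weights["inframe_indel"]
    if_background: list[str] = []
    while len(if_background) < 6:
        codon = int(rng.integers(5, model.n_codons - 5))
        start = (codon - 1) * 3 + 1
        hgvs = f"c.{start}_{start + 2}del"
        if hgvs not in taken:
            taken.add(hgvs)
            if_background.append(hgvs)
    for hgvs in if_background:
        menu.append(MenuEntry(hgvs, "inframe_indel", w_if / len(if_background)))

    # --- splice: intron-6 acceptor trio at 22% (equal split) + other signals
    w_sp = class_weights["splice"]
    for alt in ("G", "T", "C"):
        menu.append(MenuEntry(f"c.673-2A>{alt}", "splice", w_sp * 0.22 / 3))
    other_signals: list[str] = []
    for intron in model.introns:
        if intron.donor_anchor is not None:
            other_signals.append(f"c.{intron.donor_anchor}+1G>A")
            other_signals.append(f"c.{intron.donor_anchor}+2T>C")
        if intron.acceptor_anchor is not None and intron.number != 6:
            other_signals.append(f"c.{intron.acceptor_anchor}-2A>G")
            other_signals.append(f"c.{intron.acceptor_anchor}-1G>A")
    for hgvs in other_signals:
        menu.append(MenuEntry(hgvs, "splice", w_sp * 0.78 / len(other_signals)))

    return menu


def substitution_menu_by_events(
    model: GeneModel, event_weights: dict, n_per_event: int = 20, seed: int = 0
) -> list[MenuEntry]:
    """A pure-substitution menu with exact per-event weights (for
    spectrum-recovery experiments)."""
    rng = np.random.default_rng(seed)
    menu: list[MenuEntry] = []
    taken: set[str] = set()
    for event, weight in event_weights.items():
        picked: list[str] = []
        while len(picked) < n_per_event:
            pos = int(rng.integers(1, model.n_codons * 3 + 1))
            hgvs = _substitution_at(model, pos, event, rng)
            if hgvs and hgvs not in taken:
                taken.add(hgvs)
                picked.append(hgvs)
        for hgvs in picked:
            menu.append(MenuEntry(hgvs, "substitution", weight / n_per_event))
    return menu


# -- cohort simulation --------------------------------------------------

def _draw_fractions(rng, k: int, min_fraction: float = 2.1) -> np.ndarray:
    """Clone cell fractions in percent, summing to < 100, each above the
    level that keeps VAF over the 1% reporting cutoff."""
    for _ in range(200):
        # log-uniform tumor burden: minor clones dominate, as in CLL
        burden = float(np.exp(rng.uniform(np.log(0.045), np.log(0.92))))
        raw = rng.dirichlet(np.ones(k))
        fractions = 100.0 * burden * raw
        if (fractions >= min_fraction).all():
            return fractions
    fractions = np.maximum(fractions, min_fraction)
    fractions *= min(1.0, 99.0 / fractions.sum())
    return np.maximum(fractions, min_fraction)


def _pathogenicity(rng, var_class: str) -> str:
    if var_class in ("frameshift", "nonsense", "splice"):
        return "P"
    r = rng.random()
    return "P" if r < 0.45 else ("LP" if r < 0.80 else "VUS")


def simulate_cohort(
    n_patients: int,
    seed: int,
    model: GeneModel | None = None,
    menu: list[MenuEntry] | None = None,
    multiclonality_weights: tuple = DEFAULT_MULTICLONALITY_WEIGHTS,
    sanger_fraction: float = 0.25,
    cnloh_rate: float = 0.03,
    del17p_rate: float = 0.20,
    fish_tested_fraction: float = 0.61,
    vaf_decimals: int = 1,
) -> tuple[pd.DataFrame, list[ClonalArchitecture]]:
    """Draw a cohort variant table plus its ground-truth architectures.

    Reproducible given ``seed``; the returned DataFrame uses the cohort
    TSV schema consumed by :func:`tp53kit.cohort.load_cohort`.
    """
    if abs(sum(multiclonality_weights) - 1.0) > 1e-9:
        raise Tp53KitError("multiclonality weights must sum to 1")
    model = model or tp53_model()
    menu = menu or default_variant_menu(model)
    rng = np.random.default_rng(seed)
    weights = np.array([entry.weight for entry in menu], dtype=float)
    weights /= weights.sum()
    sanger_ok = np.array(
        [
            SANGER_REGION[0] <= parse_hgvs_c(entry.hgvs).start <= SANGER_REGION[1]
            for entry in menu
        ]
    )

    rows: list[dict] = []
    truths: list[ClonalArchitecture] = []
    for i in range(n_patients):
        pid = f"SIM_{i:05d}"
        is_sanger = rng.random() < sanger_fraction
        if is_sanger:
            n_variants = 1 if rng.random() < 0.88 else 2
            idx_pool = np.flatnonzero(sanger_ok)
            w = weights[idx_pool] / weights[idx_pool].sum()
            picks = rng.choice(idx_pool, size=n_variants, replace=False, p=w)
            clones = tuple(
                Clone(
                    fraction=float(f),
                    variants=(menu[j].hgvs,),
                    phase={menu[j].hgvs: "A"},
                )
                for j, f in zip(picks, _draw_fractions(rng, n_variants))
            )
            truths.append(ClonalArchitecture(pid, clones))
            for j in picks:
                rows.append(
                    {
                        "patient_id": pid,
                        "assay": "Sanger",
                        "hgvs_c": menu[j].hgvs,
                        "vaf": "",
                        "pathogenicity": _pathogenicity(rng, menu[j].var_class),
                        "del17p": "unknown",
                        "treatment": "",
                    }
                )
            continue

        mclass = int(rng.choice(4, p=np.asarray(multiclonality_weights)))
        if mclass == 0:
            n_variants = 1
        elif mclass == 1:
            n_variants = 2
        elif mclass == 2:
            n_variants = 3
        else:
            n_variants = 4 + min(int(rng.geometric(0.45)) - 1, 10)
        picks = rng.choice(len(menu), size=n_variants, replace=False, p=weights)

        fish_tested = rng.random() < fish_tested_fraction
        del17p = fish_tested and rng.random() < del17p_rate
        cnloh = (
            n_variants == 1
            and not del17p
            and fish_tested
            and rng.random() < cnloh_rate
        )
        del17p_status = ("yes" if del17p else "no") if fish_tested else "unknown"

        loh_fraction = None
        if cnloh:
            fraction = float(rng.uniform(52.0, 98.0))
            hgvs = menu[picks[0]].hgvs
            clones = (Clone(fraction, (hgvs,), {hgvs: "A"}),)
            vafs = [fraction]  # homozygous clone: VAF tracks the cell fraction
            loh_fraction = float(rng.uniform(95.0, 100.0))  # LOH itself near-clonal
        elif del17p and n_variants == 1:
            fraction = float(rng.uniform(10.0, 95.0))
            hgvs = menu[picks[0]].hgvs
            clones = (Clone(fraction, (hgvs,), {hgvs: "A"}),)
            vafs = [fraction]  # hemizygous locus
            loh_fraction = float(rng.uniform(90.0, 100.0))
        else:
            fractions = _draw_fractions(rng, n_variants)
            clones = tuple(
                Clone(float(f), (menu[j].hgvs,), {menu[j].hgvs: "A"})
                for j, f in zip(picks, fractions)
            )
            vafs = [f / 2.0 for f in fractions]  # diploid heterozygous

        germline = tuple(
            f"SNP{k + 1:02d}" for k in range(11) if rng.random() < 0.45
        )
        truths.append(
            ClonalArchitecture(
                pid, clones, germline, cnloh=cnloh, del17p=del17p,
                loh_fraction=loh_fraction,
            )
        )
        treated = rng.random() < 0.5
        for j, vaf in zip(picks, vafs):
            entry = menu[j]
            treatment = ""
            if treated:
                treatment = "CLB" if entry.hgvs in ("c.700T>C", "c.701A>G") else "FCR"
            rows.append(
                {
                    "patient_id": pid,
                    "assay": "NGS",
                    "hgvs_c": entry.hgvs,
                    "vaf": f"{max(round(vaf, vaf_decimals), 1.0):.{vaf_decimals}f}",
                    "pathogenicity": _pathogenicity(rng, entry.var_class),
                    "del17p": del17p_status,
                    "treatment": treatment,
                }
            )
    return pd.DataFrame(rows), truths


def write_cohort_tsv(df: pd.DataFrame, path: Path | str) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_truth_json(truths: list[ClonalArchitecture], path: Path | str) -> None:
    payload = [asdict(t) for t in truths]
    Path(path).write_text(json.dumps(payload, indent=1))


# -- read simulation ----------------------------------------------------

def _alleles_of(architecture: ClonalArchitecture) -> list[tuple[float, tuple]]:
    """Expand clones into (weight, alt-variant tuple) allele draws.

    Each clone contributes its two alleles at half its cell fraction: the
    phased allele carries that allele's variants, the other is wild type
    (unless CN-LOH/del17p makes the locus effectively single-allele).
    The wild-type residual contributes fully wild-type alleles.
    """
    single_allele = architecture.cnloh or architecture.del17p
    draws: list[tuple[float, tuple]] = []
    for clone in architecture.clones:
        on_a = tuple(sorted(v for v, allele in clone.phase.items() if allele == "A"))
        on_b = tuple(sorted(v for v, allele in clone.phase.items() if allele == "B"))
        if single_allele:
            draws.append((clone.fraction, on_a or on_b))
        else:
            draws.append((clone.fraction / 2.0, on_a))
            draws.append((clone.fraction / 2.0, on_b))
    wt = architecture.wildtype_fraction
    if wt > 0:
        draws.append((wt, ()))
    return draws


def simulate_read_observations(
    architecture: ClonalArchitecture,
    depth: int,
    per_site_error: float = 0.0,
    seed: int = 0,
    variants: list[str] | None = None,
) -> list[ReadObservation]:
    """Amplicon-style reads as per-variant call observations.

    Every read spans every variant position (long-read / SMRT abstraction;
    for the short-read case restrict ``variants`` to the pair of
    interest).  ``per_site_error`` is the probability that the call at a
    site flips to the opposite allele.
    """
    if depth <= 0:
        raise Tp53KitError("depth must be positive")
    rng = np.random.default_rng(seed)
    all_variants = variants or sorted(
        {v for clone in architecture.clones for v in clone.variants}
    )
    draws = _alleles_of(architecture)
    weights = np.array([w for w, _ in draws], dtype=float)
    weights /= weights.sum()
    observations = []
    for read_index in range(depth):
        _, alts = draws[int(rng.choice(len(draws), p=weights))]
        calls = {}
        for v in all_variants:
            truth = "alt" if v in alts else "ref"
            if per_site_error > 0 and rng.random() < per_site_error:
                truth = "ref" if truth == "alt" else "alt"
            calls[v] = truth
        observations.append(ReadObservation(f"read_{read_index:06d}", calls))
    return observations


def write_read_tsv(observations: list[ReadObservation], path: Path | str) -> None:
    variants = sorted({k for obs in observations for k in obs.allele_calls})
    with open(path, "w") as fh:
        fh.write("read_id\t" + "\t".join(variants) + "\n")
        for obs in observations:
            fh.write(
                obs.read_id
                + "\t"
                + "\t".join(obs.call(v) for v in variants)
                + "\n"
            )


def simulate_sam(
    model: GeneModel,
    architecture: ClonalArchitecture,
    path: Path | str,
    depth: int = 200,
    per_site_error: float = 0.0,
    read_length: int = 150,
    seed: int = 0,
) -> list[str]:
    """Write aligned reads as SAM over the spliced CDS reference.

    Supports substitution and deletion variants (the phasing-relevant
    kinds); reads are placed to span all variant positions, so
    ``read_length`` must cover their window.  Returns the variant strings
    covered.
    """
    if depth <= 0:
        raise Tp53KitError("depth must be positive")
    rng = np.random.default_rng(seed)
    cds = model.cds_sequence
    parsed = {}
    for clone in architecture.clones:
        for hgvs in clone.variants:
            v = parse_hgvs_c(hgvs)
            if v.is_intronic or v.kind not in ("substitution", "deletion"):
                raise Tp53KitError(
                    f"SAM simulation supports exonic substitutions/deletions, not {hgvs}"
                )
            parsed[hgvs] = v
    positions = [p for v in parsed.values() for p in v.span]
    lo, hi = min(positions), max(positions)
    if hi - lo + 1 > read_length - 20:
        raise Tp53KitError("read_length too short to span the variant window")
    start0 = max(0, (lo - 1) - max(5, (read_length - (hi - lo + 1)) // 2))
    start0 = min(start0, len(cds) - read_length)

    draws = _alleles_of(architecture)
    weights = np.array([w for w, _ in draws], dtype=float)
    weights /= weights.sum()

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": model.transcript_id + "_CDS", "LN": len(cds)}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read_index in range(depth):
            _, alts = draws[int(rng.choice(len(draws), p=weights))]
            seq_parts: list[str] = []
            cigar: list[tuple[int, int]] = []
            ref_pos = start0
            end0 = start0 + read_length
            dels = sorted(
                (parsed[h].span for h in alts if parsed[h].kind == "deletion"),
            )
            subs = {
                parsed[h].start - 1: parsed[h].alt
                for h in alts
                if parsed[h].kind == "substitution"
            }
            while ref_pos < end0:
                in_del = next(
                    ((dlo, dhi) for dlo, dhi in dels if dlo - 1 <= ref_pos <= dhi - 1),
                    None,
                )
                if in_del:
                    dlo, dhi = in_del
                    span = min(dhi - 1, end0 - 1) - ref_pos + 1
                    cigar.append((2, span))  # D
                    ref_pos += span
                    continue
                base = subs.get(ref_pos, cds[ref_pos])
                if per_site_error > 0 and ref_pos in subs and rng.random() < per_site_error:
                    base = cds[ref_pos]  # error flips alt back to ref
                elif (
                    per_site_error > 0
                    and any(parsed[h].start - 1 == ref_pos for h in parsed)
                    and ref_pos not in subs
                    and rng.random() < per_site_error
                ):
                    hit = next(h for h in parsed if parsed[h].start - 1 == ref_pos)
                    if parsed[hit].kind == "substitution":
                        base = parsed[hit].alt  # error fabricates the alt
                seq_parts.append(base)
                if cigar and cigar[-1][0] == 0:
                    cigar[-1] = (0, cigar[-1][1] + 1)
                else:
                    cigar.append((0, 1))
                ref_pos += 1
            read = pysam.AlignedSegment()
            read.query_name = f"read_{read_index:06d}"
            read.query_sequence = "".join(seq_parts)
            read.reference_id = 0
            read.reference_start = start0
            read.mapping_quality = 60
            read.cigartuples = cigar
            read.flag = 0
            out.write(read)
    return sorted(parsed)


# -- SNP profile simulation ---------------------------------------------

DEFAULT_SNP_PANEL = tuple(f"SNP{k + 1:02d}" for k in range(11))


def simulate_snp_profile(
    architecture: ClonalArchitecture,
    panel: tuple = DEFAULT_SNP_PANEL,
    depth: int = 1000,
    seed: int = 0,
    base_error: float = 0.002,
) -> SNPProfile:
    """Binomially sampled allele fractions for a locus SNP panel.

    Germline-heterozygous SNPs sit at expected alt fraction 0.5; a CN-LOH
    clone of cell fraction f pushes each het SNP by f/2 toward 0 or 1
    (direction drawn per SNP).  A del(17p) clone behaves the same way
    (allele loss also skews the fraction).  Panel SNPs that are not
    germline-het read near 0 or 1 apart from sequencing error.
    """
    if not panel:
        raise Tp53KitError("empty SNP panel")
    rng = np.random.default_rng(seed)
    skew_fraction = 0.0
    if architecture.cnloh or architecture.del17p:
        loh = architecture.loh_fraction
        if loh is None:
            loh = sum(c.fraction for c in architecture.clones)
        skew_fraction = loh / 100.0
    snps = []
    for index, snp_id in enumerate(panel):
        snp_depth = max(1, int(rng.poisson(depth)))
        if snp_id in architecture.germline_het_snps:
            direction = 1 if rng.random() < 0.5 else -1
            p = 0.5 + direction * skew_fraction / 2.0
        else:
            p = base_error if rng.random() < 0.5 else 1.0 - base_error
        p = min(max(p, 0.0), 1.0)
        alt = int(rng.binomial(snp_depth, p))
        snps.append((snp_id, index + 1, alt / snp_depth, snp_depth))
    return SNPProfile(architecture.patient_id, snps)
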