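"""Cohort-level statistics over annotated TP53 variant tables.

Input schema (TSV with named headers): ``patient_id``, ``assay``
(NGS|Sanger), ``hgvs_c``, and optional ``vaf`` (percent, NGS only),
``pathogenicity`` (P/LP/VUS/LB/B), ``del17p`` (yes/no/unknown),
``treatment``.

Denominators are fixed explicitly: class and event spectra are per
variant; multiclonality is per patient over the NGS subset (Sanger cannot
resolve low-VAF clones); hotspot shares are per class subset (frameshifts
for the codon-209 deletion, splice variants for the intron-6 acceptor).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError, Tp53KitError
from .hgvs import (
    EVENT_CLASSES,
    VAR_CLASSES,
    CodingVariant,
    VariantAnnotation,
    classify_variant,
    format_hgvs_c,
    normalize_indel,
    parse_hgvs_c,
)
from .reference import GeneModel, cdna_to_codon, splice_signal_catalogue

REQUIRED_COLUMNS = ("patient_id", "assay", "hgvs_c")
OPTIONAL_COLUMNS = ("vaf", "pathogenicity", "del17p", "treatment")
MULTICLONALITY_LABELS = ("SM", "DM", "MM3", "MM4plus")


@dataclass
class PatientRecord:
    patient_id: str
    assay: str  # NGS | Sanger
    del17p: str = "unknown"  # yes | no | unknown
    treatment: str | None = None
    variants: list[tuple[CodingVariant, float | None]] = field(default_factory=list)
    annotations: list[VariantAnnotation] = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def multiclonality_class(self) -> str:
        n = self.n_variants
        if n <= 1:
            return "SM"
        if n == 2:
            return "DM"
        if n == 3:
            return "MM3"
        return "MM4plus"

    @property
    def vafs(self) -> list[float | None]:
        return [vaf for _, vaf in self.variants]


@dataclass
class CohortLoadResult:
    patients: list[PatientRecord]
    row_errors: list[tuple[int, str, str]]  # (row number, hgvs_c, message)

    @property
    def n_variants(self) -> int:
        return sum(p.n_variants for p in self.patients)


def load_cohort(
    table: Path | str | pd.DataFrame,
    model: GeneModel,
    vaf_cutoff: float = 1.0,
    normalize: bool = True,
) -> CohortLoadResult:
    """Read, parse, normalize and annotate a cohort variant table.

    Duplicate variants within a patient (after normalization) collapse to
    one entry; rows whose HGVS fails to parse or whose VAF is out of range
    are collected in ``row_errors`` rather than silently dropped.  Missing
    required columns raise :class:`SchemaError`.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing required columns: {missing}")

    patients: dict[str, PatientRecord] = {}
    row_errors: list[tuple[int, str, str]] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        pid = str(getattr(row, "patient_id")).strip()
        assay = str(getattr(row, "assay")).strip()
        hgvs_text = str(getattr(row, "hgvs_c")).strip()
        if assay not in ("NGS", "Sanger"):
            row_errors.append((row_number, hgvs_text, f"unknown assay {assay!r}"))
            continue
        vaf_text = str(getattr(row, "vaf", "")).strip()
        vaf: float | None = None
        if assay == "NGS":
            if not vaf_text:
                row_errors.append((row_number, hgvs_text, "NGS row without VAF"))
                continue
            try:
                vaf = float(vaf_text)
            except ValueError:
                row_errors.append((row_number, hgvs_text, f"non-numeric VAF {vaf_text!r}"))
                continue
            if not (0 < vaf <= 100):
                row_errors.append((row_number, hgvs_text, f"VAF {vaf} outside (0, 100]"))
                continue
            if vaf < vaf_cutoff:
                row_errors.append(
                    (row_number, hgvs_text, f"VAF {vaf} below the {vaf_cutoff}% reporting cutoff")
                )
                continue
        label = str(getattr(row, "pathogenicity", "")).strip() or None
        try:
            variant = parse_hgvs_c(hgvs_text)
            if normalize:
                variant = normalize_indel(variant, model)
            annotation = classify_variant(variant, model, pathogenicity_label=label)
        except Tp53KitError as exc:
            row_errors.append((row_number, hgvs_text, str(exc)))
            continue

        record = patients.get(pid)
        if record is None:
            record = PatientRecord(
                patient_id=pid,
                assay=assay,
                del17p=str(getattr(row, "del17p", "")).strip() or "unknown",
                treatment=str(getattr(row, "treatment", "")).strip() or None,
            )
            patients[pid] = record
        elif record.assay == "Sanger" and assay == "NGS":
            record.assay = "NGS"  # NGS supersedes Sanger resolution
        seen = {format_hgvs_c(v) for v, _ in record.variants}
        if format_hgvs_c(variant) in seen:
            continue
        record.variants.append((variant, vaf))
        record.annotations.append(annotation)

    return CohortLoadResult(list(patients.values()), row_errors)


def _all_annotations(patients: list[PatientRecord]) -> list[VariantAnnotation]:
    return [a for p in patients for a in p.annotations]


def class_spectrum(patients: list[PatientRecord]) -> dict[str, float]:
    """Proportion of each variant class over all variants."""
    annotations = _all_annotations(patients)
    if not annotations:
        raise Tp53KitError("empty cohort")
    counts = {c: 0 for c in VAR_CLASSES}
    for a in annotations:
        counts[a.var_class] += 1
    total = len(annotations)
    return {c: n / total for c, n in counts.items()}


def event_spectrum(patients: list[PatientRecord]) -> dict[str, float]:
    """Proportion of each of the six strand-symmetric substitution classes,
    over substitutions only."""
    events = [a.event for a in _all_annotations(patients) if a.event in EVENT_CLASSES]
    if not events:
        raise Tp53KitError("cohort contains no substitutions")
    return {e: events.count(e) / len(events) for e in EVENT_CLASSES}


def multiclonality(
    patients: list[PatientRecord], ngs_only: bool = True
) -> dict[str, object]:
    """Per-patient variant-count classes and the cohort histogram.

    SM = one variant, DM = two, MM3 = three, MM4plus = more than three.
    """
    subset = [p for p in patients if p.assay == "NGS"] if ngs_only else list(patients)
    histogram = {label: 0 for label in MULTICLONALITY_LABELS}
    per_patient: dict[str, str] = {}
    counts: list[int] = []
    for p in subset:
        label = p.multiclonality_class
        histogram[label] += 1
        per_patient[p.patient_id] = label
        counts.append(p.n_variants)
    multi = [n for n in counts if n >= 2]
    return {
        "histogram": histogram,
        "per_patient": per_patient,
        "n_patients": len(subset),
        "n_multi": len(multi),
        "fraction_multi": len(multi) / len(subset) if subset else 0.0,
        "range": (min(multi), max(multi)) if multi else None,
    }


def cumulated_vaf(patient: PatientRecord) -> tuple[float, bool]:
    """Sum of a patient's VAFs and whether it exceeds 100% (which would
    imply overlapping clones / allele sharing)."""
    if any(vaf is None for vaf in patient.vafs):
        raise Tp53KitError(
            f"patient {patient.patient_id}: cumulated VAF needs VAFs for every variant"
        )
    total = float(sum(patient.vafs))
    return total, total > 100.0


def low_vaf_census(
    patients: list[PatientRecord], lo: float = 1.0, hi: float = 5.0
) -> dict[str, int]:
    """Patients (NGS subset) with at least one variant VAF in [lo, hi],
    split by single- vs multi-mutated status."""
    if lo >= hi:
        raise Tp53KitError(f"empty VAF band [{lo}, {hi}]")
    subset = [p for p in patients if p.assay == "NGS"]
    n_any = n_single = n_multi = 0
    for p in subset:
        in_band = [vaf for vaf in p.vafs if vaf is not None and lo <= vaf <= hi]
        if not in_band:
            continue
        n_any += 1
        if p.n_variants == 1:
            n_single += 1
        else:
            n_multi += 1
    return {"patients": n_any, "single_mutated": n_single, "multi_mutated": n_multi}


@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: cohorts; cols: focal, rest
    statistic: float | None  # chi-square value (None when Fisher was used)
    p_value: float
    odds_ratio: float
    method: str  # chi2 | fisher


def hotspot_enrichment(
    count_focal_a: int, count_total_a: int, count_focal_b: int, count_total_b: int
) -> EnrichmentResult:
    """2x2 enrichment test of a focal variant between two cohorts.

    Pearson chi-square without continuity correction by default; automatic
    Fisher exact fallback when any expected cell is below 5.  The odds
    ratio uses the Haldane 0.5 correction when a cell is zero.
    """
    if count_total_a <= 0 or count_total_b <= 0:
        raise Tp53KitError("cohort totals must be positive")
    if count_focal_a > count_total_a or count_focal_b > count_total_b:
        raise Tp53KitError("focal counts cannot exceed totals")
    if min(count_focal_a, count_focal_b) < 0:
        raise Tp53KitError("counts must be non-negative")
    table = np.array(
        [
            [count_focal_a, count_total_a - count_focal_a],
            [count_focal_b, count_total_b - count_focal_b],
        ]
    )
    expected = stats.contingency.expected_freq(table)
    a, b, c, d = table.ravel().astype(float)
    if 0 in (a, b, c, d):
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    if (expected < 5).any():
        _, p = stats.fisher_exact(table)
        return EnrichmentResult(tuple(map(tuple, table)), None, float(p), float(odds), "fisher")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return EnrichmentResult(tuple(map(tuple, table)), float(chi2), float(p), float(odds), "chi2")


def frameshift_codon_distribution(patients: list[PatientRecord]) -> dict[int, float]:
    """Per-codon frequencies among frameshift variants.

    The codon of a frameshift is the codon containing the first
    deleted/inserted base after 3' normalization (carried on the
    annotation).  Frequencies sum to 1 over frameshift variants.
    """
    codons = [
        a.codon for a in _all_annotations(patients) if a.var_class == "frameshift"
    ]
    if not codons:
        raise Tp53KitError("cohort contains no frameshift variants")
    total = len(codons)
    return {codon: codons.count(codon) / total for codon in sorted(set(codons))}


def splice_signal_distribution(
    patients: list[PatientRecord], model: GeneModel
) -> dict[str, object]:
    """Frequencies of splice variants over the canonical signal catalogue.

    The two positions of each signal are pooled under the signal key
    ("intron6_acceptor") and also reported separately by coordinate
    ("673-2").  Frequencies are over splice variants.
    """
    splice = [a for a in _all_annotations(patients) if a.var_class == "splice"]
    if not splice:
        raise Tp53KitError("cohort contains no splice variants")
    total = len(splice)
    pooled = {
        f"intron{s.intron_number}_{s.side}": 0
        for s in splice_signal_catalogue(model)
    }
    by_position: dict[str, int] = {}
    unmatched = 0
    for a in splice:
        v = a.variant
        position = f"{v.start}{v.start_offset:+d}"
        by_position[position] = by_position.get(position, 0) + 1
        if a.splice_signal is not None:
            key = f"intron{a.splice_signal.intron_number}_{a.splice_signal.side}"
            pooled[key] += 1
        else:
            unmatched += 1
    return {
        "by_signal": {k: n / total for k, n in pooled.items()},
        "by_position": {k: n / total for k, n in sorted(by_position.items())},
        "n_splice_variants": total,
        "unmatched": unmatched,
    }


def vaf_group_comparison(
    patients: list[PatientRecord], by: str = "pathogenicity"
) -> dict[str, object]:
    """Pairwise two-sided rank-sum (Mann-Whitney U) comparison of VAF
    distributions between groups of variants.

    ``by`` is "pathogenicity" (P/LP/VUS/... labels) or "recurrence"
    (variants binned by how many patients carry them: unique, 2-4, >=5).
    Groups with fewer than two VAF observations are skipped with a notice.
    Fully degenerate pairs (every observation identical) report p = 1 by
    convention, since the rank-sum statistic is undefined there.
    """
    groups: dict[str, list[float]] = {}
    if by == "pathogenicity":
        for p in patients:
            for (v, vaf), a in zip(p.variants, p.annotations):
                if vaf is None or a.pathogenicity_label is None:
                    continue
                groups.setdefault(a.pathogenicity_label, []).append(vaf)
    elif by == "recurrence":
        occurrences: dict[str, list[float]] = {}
        for p in patients:
            for v, vaf in p.variants:
                if vaf is not None:
                    occurrences.setdefault(format_hgvs_c(v), []).append(vaf)
        for vafs in occurrences.values():
            n = len(vafs)
            label = "unique" if n == 1 else ("2-4" if n <= 4 else "5plus")
            groups.setdefault(label, []).extend(vafs)
    else:
        raise Tp53KitError(f"unknown grouping {by!r}")

    usable = {k: v for k, v in groups.items() if len(v) >= 2}
    skipped = sorted(set(groups) - set(usable))
    medians = {k: float(np.median(v)) for k, v in usable.items()}
    pairs: dict[str, float] = {}
    for g1, g2 in itertools.combinations(sorted(usable), 2):
        x, y = usable[g1], usable[g2]
        if len(set(x) | set(y)) == 1:
            pairs[f"{g1}_vs_{g2}"] = 1.0
            continue
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        pairs[f"{g1}_vs_{g2}"] = float(p)
    return {"pairwise_p": pairs, "medians": medians, "skipped_groups": skipped}
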