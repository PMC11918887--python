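"""Copy-neutral LOH inference from locus SNP allele fractions.

A TP53 variant with VAF above 50% in a tumor without del(17p) suggests
that the wild-type locus was partly or fully replaced by the mutant
allele (uniparental disomy).  The signature is homozygosity of every
informative locus SNP.  Only the dominant-clone rule is implemented:
CN-LOH restricted to minor subclones is deliberately not called, since
low-fraction clones leave the germline-heterozygous SNP pattern intact.

Defaults (het band [0.10, 0.90], minimum depth 100) are package
assumptions, exposed for configuration.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import Tp53KitError

DEFAULT_HET_BAND = (0.10, 0.90)
DEFAULT_MIN_DEPTH = 100


@dataclass(frozen=True)
class SNPCall:
    snp_id: str
    genotype: str  # het | hom_ref | hom_alt | uninformative
    alt_fraction: float
    depth: int


@dataclass(frozen=True)
class SNPProfile:
    patient_id: str
    snps: list  # of (snp_id, position, alt_fraction, depth)

    def __post_init__(self):
        for snp_id, _, alt_fraction, depth in self.snps:
            if not 0.0 <= alt_fraction <= 1.0:
                raise Tp53KitError(f"{snp_id}: alt_fraction {alt_fraction} outside [0, 1]")
            if depth <= 0:
                raise Tp53KitError(f"{snp_id}: depth must be positive")


@dataclass(frozen=True)
class CNLOHCall:
    call: str  # cn_loh | heterozygous | hemizygous | uninformative
    n_informative_snps: int
    evidence: list  # of SNPCall
    variant_vaf: float | None
    del17p: str
    reason: str


def genotype_snps(
    profile: SNPProfile,
    het_band: tuple[float, float] = DEFAULT_HET_BAND,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[SNPCall]:
    """Genotype each SNP from its alt fraction.

    het inside the band at sufficient depth; hom_ref/hom_alt outside it;
    uninformative below ``min_depth``.
    """
    if not profile.snps:
        raise Tp53KitError("empty SNP profile")
    lo, hi = het_band
    calls = []
    for snp_id, _, alt_fraction, depth in profile.snps:
        if depth < min_depth:
            genotype = "uninformative"
        elif lo <= alt_fraction <= hi:
            genotype = "het"
        else:
            genotype = "hom_alt" if alt_fraction > hi else "hom_ref"
        calls.append(SNPCall(snp_id, genotype, alt_fraction, depth))
    return calls


def infer_cnloh(
    genotypes: list[SNPCall],
    variant_vaf: float | None,
    del17p: str,
) -> CNLOHCall:
    """Dominant-clone CN-LOH decision.

    cn_loh requires variant VAF > 50%, del(17p) = no, and homozygosity of
    every informative SNP (at least one).  del(17p) = yes short-circuits to
    a hemizygous interpretation.  Any heterozygous SNP forces a
    heterozygous call — adding a het SNP can never produce cn_loh.
    """
    informative = [g for g in genotypes if g.genotype != "uninformative"]
    n = len(informative)

    def build(call: str, reason: str) -> CNLOHCall:
        return CNLOHCall(call, n, list(genotypes), variant_vaf, del17p, reason)

    if del17p == "yes":
        return build(
            "hemizygous",
            "del(17p) present: SNP homozygosity reflects hemizygosity, not CN-LOH",
        )
    if n == 0:
        return build("uninformative", "no informative SNP at the locus")
    if any(g.genotype == "het" for g in informative):
        return build("heterozygous", "heterozygous locus SNP(s) present")
    # all informative SNPs homozygous
    if variant_vaf is not None and variant_vaf > 50:
        return build(
            "cn_loh",
            f"VAF {variant_vaf}% > 50 with all {n} informative SNPs homozygous and no del(17p)",
        )
    return build(
        "uninformative",
        "all SNPs homozygous but VAF <= 50%: germline homozygosity cannot be excluded",
    )
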