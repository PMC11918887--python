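"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's own code paths: edits are applied
with plain string surgery, translation runs over the whole sequence with
a literal codon table, and statistics come from closed forms.
"""
from __future__ import annotations

_CODON_TABLE = {}
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODON_TABLE[_b1 + _b2 + _b3] = _AMINO[16 * _i + 4 * _j + _k]


def translate_full(nt: str) -> str:
    """Translate every complete codon, stops rendered as '*'."""
    return "".join(
        _CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3)
    )


def translate_to_stop(nt: str) -> tuple[str, bool]:
    prot = translate_full(nt)
    if "*" in prot:
        return prot[: prot.index("*")], True
    return prot, False


def apply_edit(cds: str, kind: str, lo: int, hi: int, alt: str = "") -> str:
    """Plain string surgery in 1-based inclusive coordinates."""
    if kind == "substitution":
        return cds[: lo - 1] + alt + cds[lo:]
    if kind == "deletion":
        return cds[: lo - 1] + cds[hi:]
    if kind == "duplication":
        return cds[:hi] + cds[lo - 1 : hi] + cds[hi:]
    if kind == "insertion":  # between lo and lo+1
        return cds[:lo] + alt + cds[lo:]
    if kind == "delins":
        return cds[: lo - 1] + alt + cds[hi:]
    raise ValueError(kind)


def classify_substitution(cds: str, pos: int, alt: str) -> str:
    """missense / nonsense / synonymous by full translate-and-diff."""
    ref_prot, _ = translate_to_stop(cds)
    alt_prot, _ = translate_to_stop(apply_edit(cds, "substitution", pos, pos, alt))
    if alt_prot == ref_prot:
        return "synonymous"
    if len(alt_prot) < len(ref_prot) and ref_prot.startswith(alt_prot):
        return "nonsense"
    return "missense"


def event_class(ref: str, alt: str) -> str:
    """Strand-symmetric event name: each base pair is written
    purine-then-pyrimidine on the strand where the reference is a
    pyrimidine (so C>T is GC>AT, C>A is GC>TA)."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    r, a = (ref, alt) if ref in "CT" else (comp[ref], comp[alt])
    return f"{comp[r]}{r}>{comp[a]}{a}"


def frameshift_name(reference_protein: str, product: str, stop_found: bool) -> str:
    """HGVS fs name recomputed directly from the two protein strings."""
    three = {
        "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
        "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
        "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
        "Y": "Tyr", "V": "Val",
    }
    i = 0
    while i < min(len(reference_protein), len(product)) and reference_protein[i] == product[i]:
        i += 1
    if i == len(product):
        if i == len(reference_protein):
            return "p.="
        return f"p.{three[reference_protein[i]]}{i + 1}Ter"
    ref3 = three[reference_protein[i]] if i < len(reference_protein) else "Ter"
    ter = str(len(product) - i + 1) if stop_found else "?"
    return f"p.{ref3}{i + 1}{three[product[i]]}fsTer{ter}"


def inverted_repeats(seq: str, arm_len: int, max_spacer: int) -> set[tuple[int, str, int]]:
    """Exhaustive enumeration of all (left_start 1-based, arm, spacer)."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    hits = set()
    for left0 in range(len(seq) - 2 * arm_len + 1):
        left = seq[left0 : left0 + arm_len]
        rc = "".join(comp[b] for b in reversed(left))
        for spacer in range(max_spacer + 1):
            right0 = left0 + arm_len + spacer
            right = seq[right0 : right0 + arm_len]
            if len(right) < arm_len:
                break
            if right == rc:
                hits.add((left0 + 1, left, spacer))
    return hits


def chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square, no continuity correction, from the closed form
    sum((O-E)^2 / E)."""
    n = a + b + c + d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    total = 0.0
    for obs, r, col in ((a, row1, col1), (b, row1, col2), (c, row2, col1), (d, row2, col2)):
        expected = r * col / n
        total += (obs - expected) ** 2 / expected
    return total
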