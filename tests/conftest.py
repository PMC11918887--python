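import numpy as np
import pytest

from tp53kit.reference import build_gene_model, tp53_model


@pytest.fixture(scope="session")
def model():
    """Packaged TP53 gene model (session-scoped; the model is immutable)."""
    return tp53_model()


TOY_CDS = "ATGGCTGAAACCTTCGGATCACTTAAATAA"  # 30 nt, 9-residue product
# donor GT .. cryptic AG .. 7-nt retained tail ending in the canonical AG
TOY_INTRON = "GT" + "CTTCTT" + "AG" + "TTTCCAG"


@pytest.fixture(scope="session")
def toy_model():
    """Two-exon, one-intron synthetic gene with one cryptic acceptor."""
    return build_gene_model(
        "TOY_TX",
        "TOY_PROT",
        TOY_CDS,
        [(1, 1, 15), (2, 16, 30)],
        intron_sequences={1: TOY_INTRON},
    )


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A valid CDS: ATG + random non-stop codons + TAA."""
    bases = "ACGT"
    middle = []
    while len(middle) < n_codons - 2:
        codon = "".join(rng.choice(list(bases), size=3))
        if codon not in ("TAA", "TAG", "TGA"):
            middle.append(codon)
    return "ATG" + "".join(middle) + "TAA"
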