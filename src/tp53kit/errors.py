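"""Exception hierarchy.

Exit-code mapping used by the CLI: SchemaError -> 2, CapabilityError -> 3,
anything else -> 1.
"""


class Tp53KitError(Exception):
    """Base class for all package errors."""


class HgvsParseError(Tp53KitError):
    """Malformed HGVS c. description; message names the offending token."""


class UnsupportedHgvsError(Tp53KitError):
    """Syntactically valid HGVS feature outside the supported subset."""


class ReferenceMismatchError(Tp53KitError):
    """Stated reference allele disagrees with the gene-model sequence."""


class CoordinateError(Tp53KitError):
    """cDNA coordinate outside the CDS, or intronic where exonic required."""


class SchemaError(Tp53KitError):
    """Input table violates the documented column/value schema."""


class CapabilityError(Tp53KitError):
    """Requested computation needs data the model does not carry
    (e.g. splice-consequence prediction without the intron sequence)."""
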