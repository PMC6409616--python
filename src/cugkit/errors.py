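"""Exception hierarchy for cugkit.

All library errors derive from :class:`CugkitError` so callers (and the CLI)
can distinguish domain failures from programming errors.
"""


class CugkitError(Exception):
    """Base class for all cugkit domain errors."""


class AlphabetError(CugkitError):
    """A sequence contains characters outside the permitted alphabet."""


class FrameError(CugkitError):
    """A coding sequence is not a whole number of codons."""


class UsageTableError(CugkitError):
    """A codon-usage table is empty, malformed, or unusable."""


class RecodingError(CugkitError):
    """A recoding operation cannot satisfy its constraints."""


class InferenceError(CugkitError):
    """Code inference received unusable inputs."""


class NotATRNAError(CugkitError):
    """No qualifying anticodon placement was found in a putative tRNA."""


class DigestError(CugkitError):
    """Restriction digest or inverse-PCR simulation failed a precondition."""


class JunctionError(CugkitError):
    """A junction sequence cannot be interpreted against the cassette."""


class FastaError(CugkitError):
    """A FASTA file is empty, has duplicate ids, or is malformed."""
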