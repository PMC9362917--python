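"""Exception hierarchy for the csd T-RFLP toolkit.

Every failure mode that excludes a sequence or a worker from an analysis has
its own class so that rejects reports can carry a machine-readable reason.
"""


class CsdTrflpError(Exception):
    """Base class for all toolkit errors."""


class PrimerNotFound(CsdTrflpError):
    """A primer has no match on the expected strand of the input sequence."""


class MultipleAmplicons(CsdTrflpError):
    """More than one non-overlapping forward/reverse primer pairing exists."""


class NoRestrictionSite(CsdTrflpError):
    """The amplicon carries no ATTAAT site; the allele is atypical."""


class AmbiguousSequence(CsdTrflpError):
    """Degenerate bases make the restriction pattern undefined."""


class IntronNotFound(CsdTrflpError):
    """No intron candidate under the chosen locating strategy."""


class AmbiguousIntron(CsdTrflpError):
    """More than one intron candidate under the chosen strategy."""


class CorruptOrf(CsdTrflpError):
    """The coding sequence contains an internal stop codon."""


class HvrNotFound(CsdTrflpError):
    """No tyrosine/asparagine-rich window qualifies as a hypervariable region."""


class EmptyPatriline(CsdTrflpError):
    """A segregation test was requested on a patriline with zero workers."""


class DatasetTooSmall(CsdTrflpError):
    """The allele catalog is smaller than the requested subset size."""


class EditConflict(CsdTrflpError):
    """A simulated edit would destroy the open reading frame or the VspI site."""


class ConfigError(CsdTrflpError):
    """A simulation or pipeline configuration is internally inconsistent."""
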