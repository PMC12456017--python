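"""Exception hierarchy shared across the package."""


class ChromidFinderError(Exception):
    """Base class for all package-specific errors."""


class FastaIOError(ChromidFinderError):
    """A FASTA file could not be read or written."""


class EmptyInputError(ChromidFinderError):
    """An input file contained no sequence records."""


class ValidationError(ChromidFinderError):
    """An input violated a structural precondition (duplicate ids, foreign ids, ...)."""


class UndefinedGCError(ChromidFinderError):
    """GC content is undefined (no non-N bases)."""


class InsufficientSequenceError(ChromidFinderError):
    """Not enough unambiguous sequence to count a single k-mer window."""


class BackendUnavailableError(ChromidFinderError):
    """A requested external backend (gene caller, HMM engine) is not usable."""


class DatabaseError(ChromidFinderError):
    """A marker database or its manifest could not be loaded."""


class ParameterError(ChromidFinderError):
    """A parameter value is outside its feasible range."""
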