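"""Exception hierarchy shared across the package."""


class Fae1PopError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(Fae1PopError):
    """Records of unequal length, empty matrices, out-of-range columns."""


class AlphabetError(Fae1PopError):
    """Sequence characters outside {A, C, G, T, N, -}."""


class MetadataError(Fae1PopError):
    """Record ids that cannot be resolved against the metadata table."""


class TreeError(Fae1PopError):
    """Newick parse failures and unresolvable node labels."""


class CorrectionDomainError(Fae1PopError):
    """Jukes-Cantor correction requested for p >= 3/4."""


class DegenerateDataError(Fae1PopError):
    """A statistic is undefined on the given data (e.g. Hb = 0 for Fst)."""


class ParameterError(Fae1PopError):
    """Invalid user-supplied parameter values."""


class ConfigError(Fae1PopError):
    """Invalid or incomplete pipeline configuration."""
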