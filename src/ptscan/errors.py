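"""Exception hierarchy for ptscan."""


class PtscanError(Exception):
    """Base class for all ptscan errors."""


class InputError(PtscanError, ValueError):
    """Invalid user-supplied value (bad sequence length, out-of-range position...)."""


class ConfigurationError(PtscanError):
    """A configuration file is missing, unparsable, or structurally wrong."""


class TableValidationError(ConfigurationError):
    """A residue-class table violates its invariants (e.g. a residue in two classes)."""


class FastaParseError(PtscanError):
    """A FASTA file could not be parsed into usable records."""
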