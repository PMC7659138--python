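"""Exception hierarchy shared across the toolkit."""


class LrmetaError(Exception):
    """Base class for all toolkit errors."""


class CommunityError(LrmetaError, ValueError):
    """Invalid community definition (molarities, abundances, genome table)."""


class ConfigError(LrmetaError, ValueError):
    """Invalid or inconsistent simulation / run configuration."""


class ParseError(LrmetaError, ValueError):
    """Malformed input file (FASTA/FASTQ/SAM/TSV)."""
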