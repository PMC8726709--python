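"""Exception hierarchy shared across the pipeline.

Exit-code mapping in the CLI: ConfigurationError -> 2, DataFormatError -> 3.
"""


class ContamCheckError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ContamCheckError):
    """Invalid run configuration: missing samples, unknown references,
    duplicate ids, absent controls."""


class DataFormatError(ContamCheckError):
    """Malformed input data: broken FASTQ records, out-of-bounds
    alignments, sequence/quality length mismatches."""
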