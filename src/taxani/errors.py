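"""Exception hierarchy shared across the package."""


class TaxaniError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(TaxaniError):
    """Malformed FASTA input (empty file, missing header, duplicate ids...)."""


class ParameterError(TaxaniError, ValueError):
    """Invalid parameter value (even k, jaccard outside [0,1], ...)."""


class SketchMismatchError(TaxaniError):
    """Sketches or databases built with incompatible (k, s, hash seed)."""


class TableFormatError(TaxaniError):
    """Malformed metadata table (missing columns, bad values...)."""


class RefDBError(TaxaniError):
    """Reference-database build or load failure."""
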