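"""Exception taxonomy shared across the package.

Three families, mirrored by distinct CLI exit codes: bad arguments
(:class:`ParameterError`), malformed files or inconsistent schedules
(:class:`FormatError`), and inputs that are structurally fine but carry no
usable information (:class:`DataError`).
"""


class ParameterError(ValueError):
    """A caller-supplied parameter is out of its documented range."""


class FormatError(ValueError):
    """An input file or schedule does not match the expected layout."""


class DataError(RuntimeError):
    """The data are too degenerate for the requested operation."""
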