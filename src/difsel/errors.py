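"""Exception hierarchy shared across the pipeline.

The CLI maps these onto stable exit codes: format/metadata problems in
input files exit 2, computation-stage failures exit 3.
"""


class DifselError(Exception):
    """Base class for all pipeline errors."""


class FormatError(DifselError):
    """An input file violates its format contract (bad field, bad line)."""


class MetadataError(FormatError):
    """A sample sheet carries an unknown or inconsistent design token."""


class ComputationError(DifselError):
    """A computation stage received inputs it cannot process."""
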