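"""Exception hierarchy.

``InputError`` marks invalid in-memory arguments (shape/range violations),
``FormatError`` marks malformed on-disk inputs. Both derive from
``GravSeqError`` so callers can catch pipeline failures with one clause.
"""


class GravSeqError(Exception):
    """Base class for all gravseq errors."""


class InputError(GravSeqError, ValueError):
    """Invalid argument values or incompatible array shapes."""


class FormatError(GravSeqError, ValueError):
    """Malformed input file (bad columns, labels, or record structure)."""
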