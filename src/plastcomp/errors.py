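"""Exception hierarchy shared across the toolkit.

``PlastcompError`` is the common base; the CLI maps ``InputError`` subtypes
to exit code 3 and everything else unexpected to 4.
"""


class PlastcompError(Exception):
    """Base class for all toolkit errors."""


class InputError(PlastcompError):
    """A problem with user-supplied input (missing file, bad format...)."""


class FormatError(InputError):
    """Malformed record; the message names the offending locus or line."""


class EmptyInputError(InputError):
    """A record or file with no sequence content."""


class RaggedAlignmentError(InputError):
    """Aligned FASTA whose rows differ in length, or with fewer than 2 rows."""


class UsageError(PlastcompError):
    """Invalid parameter combination or unknown output dialect."""


class AmbiguousPartitionError(PlastcompError):
    """The two single-copy arcs have equal length; LSC/SSC cannot be named."""


class CapacityError(PlastcompError):
    """Requested synthetic content does not fit in the requested regions."""


class IdentityError(InputError):
    """An alignment row does not reproduce the genome record it should."""


class SizeCapError(UsageError):
    """Sequences too large for the built-in aligner; use an external aligner."""
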