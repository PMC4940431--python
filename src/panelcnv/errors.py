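"""Exception hierarchy.

Everything raised deliberately by panelcnv derives from :class:`PanelCNVError`
so callers (and the CLI) can separate expected input/QC problems from bugs.
"""


class PanelCNVError(Exception):
    """Base class for all panelcnv errors."""


class FormatError(PanelCNVError):
    """A file does not conform to the expected dialect."""


class AlignmentError(PanelCNVError):
    """Targets in a coverage file do not match the interval list."""


class InputError(PanelCNVError):
    """A problem with run inputs (missing/duplicate/unreadable files)."""


class DuplicateSampleError(InputError):
    """The same sample name appears in more than one coverage file."""


class DegenerateSampleError(PanelCNVError):
    """A sample carries no usable coverage (all-zero totals)."""


class BatchSizeError(PanelCNVError):
    """Fewer samples than the batch-median reference requires."""


class InsufficientDataError(PanelCNVError):
    """Too few finite values to compute a five-number summary."""


class ConfigError(PanelCNVError):
    """Invalid configuration value or simulation specification."""
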