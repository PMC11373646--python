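"""Exception hierarchy shared across the package."""


class PanelkinError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PanelkinError):
    """A file did not conform to the expected dialect (e.g. missing column)."""


class UnsupportedDialectError(FormatError):
    """A recognised format used features outside the supported dialect."""


class IntegrityError(PanelkinError):
    """Input data is internally inconsistent (duplicates, unknown references)."""


class UsageError(PanelkinError):
    """An operation was invoked with arguments that make it undefined."""


class EmptyResultError(PanelkinError):
    """A filtering step removed every sample (or locus)."""
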