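"""Exception hierarchy for sepsipanel."""


class SepsiPanelError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SepsiPanelError):
    """Invalid generator or pipeline configuration."""


class SchemaError(SepsiPanelError):
    """Tabular input does not match the expected schema."""


class AlignmentError(SepsiPanelError):
    """Feature names do not align between data and model/params."""


class DegenerateDataError(SepsiPanelError):
    """Data too small or too degenerate for the requested operation
    (single-class labels, constant columns, undersized groups)."""
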