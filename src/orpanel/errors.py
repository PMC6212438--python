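"""Exception types shared across the pipeline stages."""


class OrPanelError(ValueError):
    """Base class for all orpanel-specific errors."""


class ParameterError(OrPanelError):
    """A model or configuration parameter is outside its valid domain."""


class DataError(OrPanelError):
    """A measured value violates an assay invariant (e.g. non-positive luminescence)."""


class StructureError(OrPanelError):
    """Tables or traces do not line up (missing cycles, mismatched panels, ...)."""


class InsufficientDataError(OrPanelError):
    """Too few replicates or paired observations for the requested statistic."""


class ConfigError(OrPanelError):
    """An invalid run configuration (e.g. a panel without a vector control)."""
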