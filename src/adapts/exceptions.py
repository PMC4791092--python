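"""Exception types shared across the package."""


class AdaptsError(Exception):
    """Base class for package-specific errors."""


class InvalidSignalError(AdaptsError, ValueError):
    """Signal values unusable for the requested operation
    (non-finite, all-zero, or non-positive where a log is needed)."""


class UnderdeterminedFitError(AdaptsError, ValueError):
    """Fewer data points than free model parameters."""


class UncertaintyUnavailableError(AdaptsError, RuntimeError):
    """The ROI cannot support a subregion-based uncertainty estimate
    (too few pixels, too few subregions, or too many failed fits)."""
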