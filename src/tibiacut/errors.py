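"""Exception hierarchy for tibiacut.

All domain errors derive from :class:`TibiacutError` so callers can catch
package failures without masking programming errors.
"""


class TibiacutError(Exception):
    """Base class for all tibiacut domain errors."""


class ImageFormatError(TibiacutError):
    """Raster input does not meet the single-channel 8-bit contract."""


class EmptyClassError(TibiacutError):
    """A threshold candidate leaves one intensity class empty; its class
    statistics (mean, variance, entropy) are undefined."""


class NoValidThresholdError(TibiacutError):
    """No threshold candidate yields two valid, non-degenerate classes."""


class IllPosedSeedsError(TibiacutError):
    """Seed generation or segmentation cannot proceed: one of the two seed
    classes is empty even at zero band width (e.g. a single-level image)."""


class MetricUndefinedError(TibiacutError):
    """A metric has no defined value for the given inputs (e.g. Dice of two
    empty masks, a 0/0 form)."""


class ValidationError(TibiacutError):
    """A measurement or specification record violates its invariants."""
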