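"""Exception hierarchy shared across the package."""


class P16FociError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(P16FociError, ValueError):
    """A ring, region or slide violates the annotation geometry contract."""


class QuantificationError(P16FociError, ValueError):
    """A slide cannot be quantified (e.g. foci present but zero tissue area)."""


class DataError(P16FociError, ValueError):
    """An input table or matrix violates its schema or value contract."""


class UndefinedMetricError(P16FociError, ValueError):
    """A requested statistic is undefined on the given data (names the metric)."""
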