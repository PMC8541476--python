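"""Exception hierarchy for the soil ICE pipeline.

Every stage raises a subclass of :class:`SoilIceError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class SoilIceError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(SoilIceError):
    """An input table is missing a mandatory column."""


class UnitConversionError(SoilIceError):
    """A concentration unit is not convertible to mg/kg soil."""


class CurationError(SoilIceError):
    """Curation configuration does not cover the data (e.g. unknown taxon)."""


class InvalidPairError(SoilIceError):
    """A species pair is ill-formed (surrogate equals predicted)."""


class InsufficientDataError(SoilIceError):
    """Too few paired chemicals to fit a regression."""


class DegeneratePredictorError(SoilIceError):
    """The surrogate values have zero variance; the slope is unidentifiable."""


class EligibilityError(SoilIceError):
    """A model does not meet the cross-validation eligibility gate."""


class UndefinedStatisticError(SoilIceError):
    """A summary statistic was requested on an empty collection."""


class ModelLookupError(SoilIceError):
    """A requested species-pair model does not exist in a model table."""
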