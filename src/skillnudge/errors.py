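"""Exception hierarchy.

All package errors derive from :class:`SkillnudgeError`. Validation errors are
split into schema problems (missing/unknown fields, unparseable values), range
violations on bounded numeric fields, and cross-field consistency violations,
because callers (and the clinician-facing CLI) treat these differently.

Subclasses deliberately do NOT inherit from ``ValueError``: pydantic v2 swallows
``ValueError`` raised inside validators and re-wraps it, whereas we want our
typed errors to propagate unchanged out of model construction.
"""


class SkillnudgeError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(SkillnudgeError):
    """A record is structurally invalid: missing, unknown, or unparseable field."""


class RangeError(SkillnudgeError):
    """A bounded field (e.g. the 1-5 mood rating) is outside its domain."""


class ConsistencyError(SkillnudgeError):
    """Fields are individually valid but jointly contradictory."""


class ParseError(SchemaError):
    """A serialized stream could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class OrderingError(SkillnudgeError):
    """Events were presented out of timestamp order."""


class ConfigurationError(SkillnudgeError):
    """The clinician configuration is incomplete or contradictory."""


class LimitError(ConfigurationError):
    """A clinician-facing cap (e.g. at most 3 active priority goals) was exceeded."""


class DependencyError(ConfigurationError):
    """A goal or template references a skill that has not been opened yet."""


class UndefinedMetricError(SkillnudgeError):
    """A metric is undefined on the given data (empty period, no responses, ...)."""


class EstimationError(SkillnudgeError):
    """Model fitting failed or the data are degenerate for the requested fit."""


class SimulationError(SkillnudgeError):
    """Simulator parameters are invalid."""
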