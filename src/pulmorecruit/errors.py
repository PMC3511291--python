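"""Exception hierarchy for pulmorecruit.

All errors derive from :class:`PulmoRecruitError` so callers can catch the
package's failures with a single ``except`` clause; most also derive from
``ValueError`` because they signal invalid inputs or configuration.
"""


class PulmoRecruitError(Exception):
    """Base class for all pulmorecruit errors."""


class ParameterError(PulmoRecruitError, ValueError):
    """A numeric parameter violates its physical or statistical constraints."""


class ConfigurationError(PulmoRecruitError, ValueError):
    """A configuration is inconsistent (e.g. TCP distribution above TOP)."""


class InfeasibleVentilationError(PulmoRecruitError, ValueError):
    """The requested ventilation cannot be delivered by the unit population."""


class InputError(PulmoRecruitError, ValueError):
    """A data input (record, curve, sample) is empty or malformed."""


class NoBreathsError(InputError):
    """No breaths could be detected in a waveform record."""


class MissingLevelError(InputError):
    """A required PEEP level has no usable breaths."""


class UnidentifiableCurveError(InputError):
    """A PV curve carries no information about the model parameters."""
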