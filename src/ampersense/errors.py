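"""Exception hierarchy for ampersense."""


class AmpersenseError(Exception):
    """Base class for all ampersense errors."""


class GridStabilityError(AmpersenseError):
    """Explicit diffusion scheme violates the von Neumann criterion.

    Raised before the solve starts; the message names the violated
    criterion (lambda = D*dt/dx^2 <= 0.5) and the offending value.
    """


class SolverDivergenceError(AmpersenseError):
    """The diffusion solve produced unphysical (negative) concentrations."""


class NoPeakFound(AmpersenseError):
    """No voltammetric peak distinguishable from the baseline residual."""


class NearReversible(AmpersenseError):
    """Peak separation too close to the Nernstian limit to resolve kinetics.

    Below ~59 mV (for n*dEp) the working curve psi(dEp) diverges and the
    standard rate constant is not recoverable from peak separation alone.
    """


class SuperNernstianRange(AmpersenseError):
    """Peak separation beyond the tabulated working curve (n*dEp > 212 mV).

    Callers should switch to the irreversible-regime estimate
    (:func:`ampersense.voltammetry.psi_extended`).
    """


class CalibrationError(AmpersenseError):
    """Calibration could not be built (too few points, non-positive slope...)."""


class NullStep(AmpersenseError):
    """A fitted current step is indistinguishable from zero."""


class ScheduleError(AmpersenseError):
    """Injection schedule inconsistent with the trace it is applied to."""


class TraceFormatError(AmpersenseError):
    """A trace file failed validation (columns, units, monotonicity, truncation)."""


class ConfigError(AmpersenseError):
    """Run configuration invalid for the requested command."""
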