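"""Exception hierarchy for the physioaffect pipeline."""


class PhysioAffectError(Exception):
    """Base class for all package-specific errors."""


class DesignError(PhysioAffectError, ValueError):
    """Invalid study design or effect model (bad quadrant label, out-of-range value)."""


class GenerationError(PhysioAffectError, ValueError):
    """Synthetic signal generation failed (e.g. a planted rate left physiological bounds)."""


class SignalError(PhysioAffectError, ValueError):
    """Signal processing failed (degenerate channel, too few detected events, bad window)."""


class ModelError(PhysioAffectError, ValueError):
    """Statistical or network model could not be fit or evaluated."""
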