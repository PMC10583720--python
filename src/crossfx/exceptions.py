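"""Package-wide exception hierarchy."""


class CrossFxError(Exception):
    """Base class for all crossfx errors."""


class CodingError(CrossFxError):
    """A variable that must be binary (or finite) carries an illegal value."""


class ArmAbsentError(CrossFxError):
    """A required treatment arm (X=0 or X=1) has no records."""


class DagCompatibilityError(CrossFxError):
    """An estimand or operation was requested under an incompatible DAG variant."""


class UnderspecifiedEffectError(CrossFxError):
    """An estimand was requested without all of its required level arguments."""


class EmptyStratumError(CrossFxError):
    """A saturated (stratified-frequency) model was queried in an empty stratum."""


class LPFailureError(CrossFxError):
    """The linear-programming solver did not report an optimal solution."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class DegenerateResamplesError(CrossFxError):
    """Bootstrap resampling repeatedly produced replicates on which the
    statistic is undefined (e.g. an empty arm)."""
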