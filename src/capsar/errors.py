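"""Exception types shared across the simulator."""


class CapsarError(Exception):
    """Base class for all simulator errors."""


class InvalidInputError(CapsarError, ValueError):
    """A caller-supplied value violates an operation precondition."""


class StageTransitionError(CapsarError):
    """A functionalization stage was requested out of order."""


class RealizationError(CapsarError):
    """Monte-Carlo capacitor-bank draw produced a non-physical unit value."""


class InvalidStateError(CapsarError):
    """Internal quantities reached a non-physical state (e.g. C_T <= 0)."""
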