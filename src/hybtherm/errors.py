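"""Exception hierarchy shared across the package."""


class HybthermError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HybthermError):
    """Unknown parameter set, preset, or invalid configuration value."""


class IntegrityError(HybthermError):
    """A packaged parameter table is malformed or incomplete."""


class AlphabetError(HybthermError, ValueError):
    """Sequence contains characters outside the expected alphabet."""


class DegenerateInputError(HybthermError, ValueError):
    """Input too small/degenerate for the requested computation."""


class NumericalDomainError(HybthermError, ArithmeticError):
    """A formula was evaluated outside its numerical domain."""


class BoundsError(HybthermError, IndexError):
    """A region or coordinate falls outside its parent sequence."""


class ConsistencyError(HybthermError, ValueError):
    """Inputs that must agree (probe vs binding site) do not."""


class InputError(HybthermError, ValueError):
    """Malformed user-facing input (tables, duplicate ids, bad values)."""


class StateError(HybthermError, RuntimeError):
    """Operation called on an object in the wrong state."""
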