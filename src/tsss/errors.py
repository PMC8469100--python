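"""Exception hierarchy shared across the package."""


class TsssError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TsssError):
    """A bundled resource or a parameter combination is unusable."""


class ParameterError(TsssError):
    """A numeric parameter is outside its legal range."""


class ResidueError(TsssError):
    """A symbol is not part of the scoring alphabet."""


class AlphabetSpecError(TsssError):
    """A fixed reduced-alphabet specification is not a valid partition."""


class InputError(TsssError):
    """Malformed user input (sequences, files, ids)."""


class IndexFormatError(TsssError):
    """An on-disk seed index could not be read back."""
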