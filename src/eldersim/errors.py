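"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid configuration (dimensions, proportions, parameter ranges)."""


class DomainError(ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class DegenerateInputError(ValueError):
    """Input on which the requested statistic is undefined (e.g. all-zero means)."""
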