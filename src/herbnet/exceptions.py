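"""Exception hierarchy shared across the pipeline stages."""


class HerbnetError(Exception):
    """Base class for all herbnet errors."""


class ParameterError(HerbnetError, ValueError):
    """A simulation spec or threshold parameter is out of its valid range."""


class InputError(HerbnetError, ValueError):
    """An input table, vector, or identifier set violates a precondition."""


class PreprocessingError(HerbnetError, ValueError):
    """Scaling or normalisation cannot proceed (e.g. a constant variable)."""


class ConfigError(HerbnetError, ValueError):
    """Pipeline configuration failed validation.

    Carries the full list of violations so callers see every problem at
    once, not just the first.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )
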