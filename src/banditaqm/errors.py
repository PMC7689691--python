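"""Exception hierarchy shared across the package."""


class BanditAqmError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BanditAqmError):
    """Input file does not have the expected shape (e.g. a missing column)."""


class ValidationError(BanditAqmError):
    """A value or combination of values violates a documented invariant."""


class ConfigError(BanditAqmError):
    """Configuration is unparseable or violates its invariants.

    Carries the full list of problems so a user can fix them in one pass.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class PoolExhaustedError(BanditAqmError):
    """A treatment pool has fewer unconsumed installations than requested."""

    def __init__(self, treatment_id, requested, remaining):
        self.treatment_id = treatment_id
        self.requested = requested
        self.remaining = remaining
        super().__init__(
            f"treatment {treatment_id!r}: requested {requested} installations "
            f"but only {remaining} remain in the pool"
        )


class InferenceError(BanditAqmError):
    """The posterior has (numerically) no mass inside the prior box."""


class DiagnosticError(BanditAqmError):
    """A convergence diagnostic was asked of draws that cannot support it."""
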