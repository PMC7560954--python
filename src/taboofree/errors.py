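"""Exception types shared across the package."""


class TabooFreeError(Exception):
    """Base class for all package-specific errors."""


class InvalidSymbolError(TabooFreeError, ValueError):
    """A string contains a symbol outside the declared alphabet."""


class InvalidTabooError(TabooFreeError, ValueError):
    """A taboo violates the basic requirements (length >= 2, alphabet symbols)."""


class NotApplicableError(TabooFreeError, RuntimeError):
    """A result was requested outside the hypotheses under which it is proven.

    Typically raised when an operation requires a left proper taboo-set but the
    given set is not left proper.
    """


class EnumerationBudgetError(TabooFreeError, RuntimeError):
    """An enumeration would exceed the configured vertex budget.

    The budget guards against accidental exponential blow-ups; pass a larger
    ``budget`` (or ``budget=None``) to force the enumeration.
    """
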