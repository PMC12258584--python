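"""Structured exceptions raised across the package.

Every error a caller is expected to branch on has its own class; messages
carry the offending identifier so failures in screening runs are diagnosable
after the fact.
"""


class KinfitError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedSBMLFeatureError(KinfitError):
    """The document uses an SBML construct outside the supported subset
    (events, delays, algebraic rules, rate rules, SBML packages)."""

    def __init__(self, feature: str, element: str = ""):
        self.feature = feature
        self.element = element
        msg = f"unsupported-SBML-feature: {feature}"
        if element:
            msg += f" ({element})"
        super().__init__(msg)


class UnresolvedSymbolError(KinfitError):
    """A rate expression references a symbol that is not a species,
    parameter, compartment, rule target, or time."""

    def __init__(self, symbol: str, where: str = ""):
        self.symbol = symbol
        super().__init__(f"unresolved-symbol: '{symbol}'" + (f" in {where}" if where else ""))


class CyclicRuleError(KinfitError):
    """Assignment rules form a cycle and cannot be flattened."""


class UnknownParameterError(KinfitError):
    """A parameter id was supplied that the model does not declare."""


class UnknownSpeciesError(KinfitError):
    """A dataset column does not match any model species."""


class UnknownMechanismError(KinfitError):
    """Requested rate law is not in the mechanism registry."""


class MissingBindingError(KinfitError):
    """A mechanism slot (species role or parameter) was left unbound."""


class RateEvaluationError(KinfitError):
    """A rate law evaluated to a non-finite flux."""

    def __init__(self, law: str, inputs=None):
        self.law = law
        self.inputs = inputs
        super().__init__(f"rate-evaluation: non-finite flux from '{law}' at {inputs}")


class ZeroMeanSpeciesError(KinfitError):
    """A dataset species has zero mean, which the mean-centered loss
    cannot normalize by."""


class NonFiniteGradientError(KinfitError):
    """Gradient contains NaN or infinity."""


class GradientUnavailableError(KinfitError):
    """Loss/gradient could not be evaluated because integration failed."""

    def __init__(self, diagnostic: str = ""):
        self.diagnostic = diagnostic
        super().__init__(f"gradient-unavailable: {diagnostic}")


class DivergedOptimizerError(KinfitError):
    """Optimizer produced a non-finite update."""


class InvalidBoundsError(KinfitError):
    """Prior bounds are invalid (e.g. non-positive reference value for a
    positivity-constrained parameter)."""


class FixtureUnsolvableError(KinfitError):
    """Synthetic-data generation failed because the model does not
    integrate at the supplied ground-truth parameters."""
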