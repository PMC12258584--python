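"""Registry of reusable kinetic rate laws.

Each :class:`RateLaw` is data, not code: named species roles (substrates,
products, modifiers), named parameter slots, and a symbolic flux expression
over those slots.  Laws are instantiated into ordinary
:class:`~kinfit.sbml.Reaction` objects, so mechanism-built models and
SBML-imported models are indistinguishable downstream.

The built-in registry covers the canonical enzyme-kinetics repertoire —
mass action (uni/bi, irreversible/reversible), irreversible and reversible
(Haldane-constrained) Michaelis–Menten, Hill activation, competitive and
non-competitive inhibition, a reduced ordered bi-bi, a symmetric
facilitated-diffusion carrier, and constant flux — and is extensible:
:func:`register_law` adds new laws, and the whole registry round-trips
through a JSON catalog.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import json
import math

import sympy

from .errors import MissingBindingError, RateEvaluationError, UnknownMechanismError
from .sbml import Reaction, _sympify_formula

__all__ = [
    "RateLaw",
    "REGISTRY",
    "register_law",
    "get_law",
    "instantiate_law",
    "evaluate_rate",
    "registry_to_json",
    "registry_from_json",
]


@dataclass(frozen=True)
class RateLaw:
    name: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    modifiers: tuple[str, ...]
    parameters: tuple[str, ...]
    expression: sympy.Expr  # over the slot symbols
    reversible: bool = False

    def __post_init__(self):
        slots = set(self.substrates + self.products + self.modifiers + self.parameters)
        free = {str(s) for s in self.expression.free_symbols}
        if not free <= slots:
            raise MissingBindingError(
                f"law '{self.name}' references undeclared slots: {sorted(free - slots)}"
            )


def _law(name, substrates, products, modifiers, parameters, expression, reversible=False):
    slots = {
        s: sympy.Symbol(s) for s in tuple(substrates) + tuple(products) + tuple(modifiers) + tuple(parameters)
    }
    return RateLaw(
        name=name,
        substrates=tuple(substrates),
        products=tuple(products),
        modifiers=tuple(modifiers),
        parameters=tuple(parameters),
        expression=_sympify_formula(expression, where=f"law '{name}'", symbols=slots),
        reversible=reversible,
    )


REGISTRY: dict[str, RateLaw] = {}


def register_law(law: RateLaw) -> RateLaw:
    REGISTRY[law.name] = law
    return law


for _l in [
    _law("mass_action_irrev_uni", ["S"], [], [], ["k"], "k * S"),
    _law("mass_action_irrev_bi", ["S1", "S2"], [], [], ["k"], "k * S1 * S2"),
    _law("mass_action_rev_uni", ["S"], ["P"], [], ["kf", "kr"], "kf * S - kr * P", True),
    _law(
        "mass_action_rev_bi",
        ["S1", "S2"],
        ["P1", "P2"],
        [],
        ["kf", "kr"],
        "kf * S1 * S2 - kr * P1 * P2",
        True,
    ),
    _law("michaelis_menten_irrev", ["S"], [], [], ["vmax", "km"], "vmax * S / (km + S)"),
    # Haldane-constrained reversible Michaelis-Menten: flux vanishes exactly
    # at P/S = keq, keeping thermodynamic consistency testable
    _law(
        "michaelis_menten_rev",
        ["S"],
        ["P"],
        [],
        ["vmax", "km_s", "km_p", "keq"],
        "(vmax / km_s) * (S - P / keq) / (1 + S / km_s + P / km_p)",
        True,
    ),
    _law(
        "hill_activation",
        ["S"],
        [],
        [],
        ["vmax", "k_half", "hill_n"],
        "vmax * S^hill_n / (k_half^hill_n + S^hill_n)",
    ),
    _law(
        "mm_competitive_inhibition",
        ["S"],
        [],
        ["I"],
        ["vmax", "km", "ki"],
        "vmax * S / (km * (1 + I / ki) + S)",
    ),
    _law(
        "mm_noncompetitive_inhibition",
        ["S"],
        [],
        ["I"],
        ["vmax", "km", "ki"],
        "vmax * S / ((km + S) * (1 + I / ki))",
    ),
    # reduced ordered bi-bi (no product inhibition terms in the denominator)
    _law(
        "ordered_bi_bi",
        ["A", "B"],
        ["P", "Q"],
        [],
        ["vmax", "km_a", "km_b", "ki_a", "keq"],
        "vmax * (A * B - P * Q / keq) / (ki_a * km_b + km_b * A + km_a * B + A * B)",
        True,
    ),
    # symmetric carrier; flux vanishes when S = P
    _law(
        "facilitated_diffusion",
        ["S"],
        ["P"],
        [],
        ["vmax", "km"],
        "vmax * (S - P) / (km + S + P)",
        True,
    ),
    _law("constant_flux", [], [], [], ["v"], "v"),
]:
    register_law(_l)


def get_law(name: str) -> RateLaw:
    if name not in REGISTRY:
        raise UnknownMechanismError(f"unknown-mechanism: '{name}'")
    return REGISTRY[name]


def instantiate_law(
    name: str,
    species: dict[str, str] | None = None,
    parameters: dict[str, str | float] | None = None,
    reaction_id: str = "",
) -> Reaction:
    """Bind a registry law's slots to concrete species and parameter ids.

    ``species`` maps substrate/product/modifier slots to species ids;
    ``parameters`` maps parameter slots to parameter ids (symbols, trainable)
    or to plain numbers (frozen constants).  Stoichiometry is one per slot
    occurrence; a species bound to two substrate slots gets coefficient 2.
    """
    law = get_law(name)
    species = dict(species or {})
    parameters = dict(parameters or {})
    for slot in law.substrates + law.products + law.modifiers:
        if slot not in species:
            raise MissingBindingError(f"missing-binding: species slot '{slot}' of '{name}'")
    for slot in law.parameters:
        if slot not in parameters:
            raise MissingBindingError(f"missing-binding: parameter slot '{slot}' of '{name}'")

    sub = {}
    for slot, sid in species.items():
        sub[sympy.Symbol(slot)] = sympy.Symbol(sid)
    for slot, val in parameters.items():
        sub[sympy.Symbol(slot)] = (
            sympy.Symbol(val) if isinstance(val, str) else sympy.Float(float(val))
        )
    rate = law.expression.xreplace(sub)

    reactants = Counter(species[s] for s in law.substrates)
    products = Counter(species[s] for s in law.products)
    modifiers = tuple(dict.fromkeys(species[s] for s in law.modifiers))
    return Reaction(
        id=reaction_id or name,
        reactants={k: float(v) for k, v in reactants.items()},
        products={k: float(v) for k, v in products.items()},
        modifiers=modifiers,
        rate=rate,
    )


def evaluate_rate(
    reaction: Reaction,
    concentrations: dict[str, float],
    parameters: dict[str, float] | None = None,
    t: float = 0.0,
) -> float:
    """Numerically evaluate one reaction's flux; non-finite results raise
    :class:`~kinfit.errors.RateEvaluationError`."""
    env = {sympy.Symbol("time"): t}
    for k, v in concentrations.items():
        env[sympy.Symbol(k)] = float(v)
    for k, v in (parameters or {}).items():
        env[sympy.Symbol(k)] = float(v)
    value = reaction.rate.xreplace(env)
    try:
        value = float(sympy.N(value))
    except TypeError as exc:
        raise RateEvaluationError(reaction.id, dict(concentrations)) from exc
    if not math.isfinite(value):
        raise RateEvaluationError(reaction.id, dict(concentrations))
    return value


# ---------------------------------------------------------------- JSON catalog


def registry_to_json(registry: dict[str, RateLaw] | None = None) -> str:
    registry = registry if registry is not None else REGISTRY
    payload = [
        {
            "name": l.name,
            "substrates": list(l.substrates),
            "products": list(l.products),
            "modifiers": list(l.modifiers),
            "parameters": list(l.parameters),
            "expression": str(l.expression),
            "reversible": l.reversible,
        }
        for l in registry.values()
    ]
    return json.dumps(payload, indent=2)


def registry_from_json(text: str) -> dict[str, RateLaw]:
    laws = {}
    for entry in json.loads(text):
        law = _law(
            entry["name"],
            entry["substrates"],
            entry["products"],
            entry["modifiers"],
            entry["parameters"],
            entry["expression"].replace("**", "^"),
            entry.get("reversible", False),
        )
        laws[law.name] = law
    return laws
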