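"""SBML import/export for kinetic models.

Reads SBML Level 2/3 documents (via libsbml) into a flattened, symbolic
:class:`ModelSpec` whose reaction rates are sympy expressions, and writes
parameterized models back out as SBML Level 3 Version 2.

Supported subset: species, compartments, global and local parameters,
reactions with MathML kinetic laws, assignment rules, initial assignments
and function definitions (inlined at parse time).  Events, delays,
algebraic rules, rate rules and SBML packages (comp, fbc, layout) are
rejected with :class:`~kinfit.errors.UnsupportedSBMLFeatureError` — narrow,
explicit support beats silent misparsing.  Units are read but never used
for computation; species are treated as concentrations (amounts are divided
by the compartment size at parse time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import sympy
from sympy.parsing.sympy_parser import (
    parse_expr,
    standard_transformations,
    convert_xor,
)

import libsbml

from .errors import (
    CyclicRuleError,
    KinfitError,
    UnknownParameterError,
    UnresolvedSymbolError,
    UnsupportedSBMLFeatureError,
)

__all__ = [
    "Species",
    "Reaction",
    "ModelSpec",
    "parse_sbml",
    "flatten_model",
    "build_stoichiometric_matrix",
    "export_sbml",
    "TIME",
]

#: canonical symbol for simulation time inside rate expressions
TIME = sympy.Symbol("time")

_PARSE_TRANSFORMS = standard_transformations + (convert_xor,)

# functions the MathML/L3-formula subset may use, mapped onto sympy
_KNOWN_FUNCTIONS = {
    "exp": sympy.exp,
    "ln": sympy.log,
    "log10": lambda x: sympy.log(x, 10),
    "sqrt": sympy.sqrt,
    "pow": sympy.Pow,
    "abs": sympy.Abs,
    "floor": sympy.floor,
    "ceiling": sympy.ceiling,
}


@dataclass(frozen=True)
class Species:
    id: str
    initial_value: float  # concentration, model units
    compartment: str
    constant: bool = False  # constant=True or boundaryCondition=True in SBML


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry maps plus a symbolic rate expression.

    Local parameters have already been renamed to ``<reaction id>__<param id>``
    by the parser; the rate expression references only declared symbols.
    """

    id: str
    reactants: dict[str, float]  # species id -> positive coefficient
    products: dict[str, float]
    modifiers: tuple[str, ...] = ()
    rate: sympy.Expr = sympy.Integer(0)

    def net_stoichiometry(self, species_id: str) -> float:
        return self.products.get(species_id, 0.0) - self.reactants.get(species_id, 0.0)


@dataclass
class ModelSpec:
    """Declarative, flattened description of a kinetic model."""

    species: list[Species]
    compartments: dict[str, float]
    global_params: dict[str, float]
    reactions: list[Reaction]
    assignment_rules: dict[str, sympy.Expr] = field(default_factory=dict)
    initial_assignments: dict[str, sympy.Expr] = field(default_factory=dict)
    function_defs: dict[str, tuple[tuple[str, ...], sympy.Expr]] = field(default_factory=dict)
    model_id: str = "model"
    flattened: bool = False

    # ------------------------------------------------------------------ views
    @property
    def dynamic_species(self) -> list[Species]:
        """Species that are part of the ODE state, in document order."""
        return [s for s in self.species if not s.constant]

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        """Check the structural invariants; raise on violation."""
        ids = (
            [s.id for s in self.species]
            + list(self.compartments)
            + list(self.global_params)
            + [r.id for r in self.reactions]
        )
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise KinfitError(f"duplicate identifiers: {sorted(dupes)}")
        for s in self.species:
            if not math.isfinite(s.initial_value):
                raise KinfitError(f"non-finite initial value for species '{s.id}'")
        for r in self.reactions:
            for coeff in list(r.reactants.values()) + list(r.products.values()):
                if not math.isfinite(coeff) or coeff <= 0:
                    raise KinfitError(f"invalid stoichiometric coefficient in '{r.id}'")
            for m in r.modifiers:
                if m in r.reactants or m in r.products:
                    raise KinfitError(f"modifier '{m}' also in stoichiometry of '{r.id}'")
            self._check_symbols(r.rate, where=f"reaction '{r.id}'")
        for target, expr in self.assignment_rules.items():
            self._check_symbols(expr, where=f"rule for '{target}'")

    def _known_symbols(self) -> set[str]:
        return (
            {s.id for s in self.species}
            | set(self.compartments)
            | set(self.global_params)
            | set(self.assignment_rules)
            | {str(TIME)}
        )

    def _check_symbols(self, expr: sympy.Expr, where: str = "") -> None:
        known = self._known_symbols()
        for sym in expr.free_symbols:
            if str(sym) not in known:
                raise UnresolvedSymbolError(str(sym), where=where)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _sympify_formula(
    formula: str, where: str = "", symbols: dict[str, sympy.Symbol] | None = None
) -> sympy.Expr:
    """Parse a libsbml L3 formula string into a sympy expression.

    ``symbols`` maps every declared model identifier to its Symbol so that
    names such as ``E`` or ``S`` are never captured by sympy builtins.
    """
    local = dict(_KNOWN_FUNCTIONS)
    if symbols:
        local.update(symbols)
    local["time"] = TIME
    try:
        expr = parse_expr(formula, local_dict=local, transformations=_PARSE_TRANSFORMS)
    except Exception as exc:  # sympy raises many types here
        raise KinfitError(f"cannot parse formula '{formula}' in {where}: {exc}") from exc
    for f in expr.atoms(sympy.Function):
        if isinstance(f, sympy.core.function.AppliedUndef):
            raise UnsupportedSBMLFeatureError("function", f"{f.func.__name__} in {where}")
    return expr


def _ast_to_sympy(node, symbols: dict[str, sympy.Symbol], where: str = "") -> sympy.Expr:
    """Convert a libsbml ASTNode directly to sympy (no string round trip,
    so numeric literals keep full binary precision)."""
    T = node.getType()
    kids = [_ast_to_sympy(node.getChild(i), symbols, where) for i in range(node.getNumChildren())]
    if T == libsbml.AST_INTEGER:
        return sympy.Integer(node.getInteger())
    if T in (libsbml.AST_REAL, libsbml.AST_REAL_E):
        return sympy.Float(node.getReal())
    if T == libsbml.AST_RATIONAL:
        return sympy.Rational(node.getNumerator(), node.getDenominator())
    if T == libsbml.AST_NAME:
        name = node.getName()
        return symbols.get(name, sympy.Symbol(name))
    if T == libsbml.AST_NAME_TIME:
        return TIME
    if T == libsbml.AST_CONSTANT_PI:
        return sympy.pi
    if T == libsbml.AST_CONSTANT_E:
        return sympy.E
    if T == libsbml.AST_PLUS:
        return sympy.Add(*kids) if kids else sympy.Integer(0)
    if T == libsbml.AST_MINUS:
        return -kids[0] if len(kids) == 1 else kids[0] - kids[1]
    if T == libsbml.AST_TIMES:
        return sympy.Mul(*kids) if kids else sympy.Integer(1)
    if T == libsbml.AST_DIVIDE:
        return kids[0] / kids[1]
    if T in (libsbml.AST_POWER, libsbml.AST_FUNCTION_POWER):
        return kids[0] ** kids[1]
    if T == libsbml.AST_FUNCTION_EXP:
        return sympy.exp(kids[0])
    if T == libsbml.AST_FUNCTION_LN:
        return sympy.log(kids[0])
    if T == libsbml.AST_FUNCTION_LOG:
        if len(kids) == 2:  # explicit base as first child
            return sympy.log(kids[1], kids[0])
        return sympy.log(kids[0], 10)
    if T == libsbml.AST_FUNCTION_ROOT:
        if len(kids) == 2:
            return kids[1] ** (sympy.Integer(1) / kids[0])
        return sympy.sqrt(kids[0])
    if T == libsbml.AST_FUNCTION_ABS:
        return sympy.Abs(kids[0])
    if T == libsbml.AST_FUNCTION_FLOOR:
        return sympy.floor(kids[0])
    if T == libsbml.AST_FUNCTION_CEILING:
        return sympy.ceiling(kids[0])
    if T == libsbml.AST_FUNCTION_DELAY:
        raise UnsupportedSBMLFeatureError("delay", where)
    if T == libsbml.AST_FUNCTION:
        raise UnsupportedSBMLFeatureError("function", f"{node.getName()} in {where}")
    raise UnsupportedSBMLFeatureError(
        "math-element", f"AST type {node.getType()} in {where}"
    )


def _math_to_expr(
    math_ast, where: str = "", symbols: dict[str, sympy.Symbol] | None = None
) -> sympy.Expr:
    if math_ast is None:
        raise KinfitError(f"missing math element in {where}")
    return _ast_to_sympy(math_ast, symbols or {}, where=where)


def _collect_symbols(model: "libsbml.Model") -> dict[str, sympy.Symbol]:
    """Symbol table of every identifier the document declares."""
    ids: set[str] = set()
    for i in range(model.getNumSpecies()):
        ids.add(model.getSpecies(i).getId())
    for i in range(model.getNumCompartments()):
        ids.add(model.getCompartment(i).getId())
    for i in range(model.getNumParameters()):
        ids.add(model.getParameter(i).getId())
    for i in range(model.getNumRules()):
        ids.add(model.getRule(i).getVariable())
    for i in range(model.getNumReactions()):
        kl = model.getReaction(i).getKineticLaw()
        if kl is not None:
            n_local = kl.getNumLocalParameters() or kl.getNumParameters()
            for j in range(n_local):
                lp = kl.getLocalParameter(j) or kl.getParameter(j)
                ids.add(lp.getId())
    ids.discard("")
    return {i: sympy.Symbol(i) for i in ids}


def _ast_uses_delay(node) -> bool:
    if node is None:
        return False
    if node.getType() == libsbml.AST_FUNCTION_DELAY:
        return True
    return any(_ast_uses_delay(node.getChild(i)) for i in range(node.getNumChildren()))


def _check_unsupported(model: "libsbml.Model") -> None:
    if model.getNumEvents() > 0:
        raise UnsupportedSBMLFeatureError("event", model.getEvent(0).getId() or "event[0]")
    for i in range(model.getNumRules()):
        rule = model.getRule(i)
        if rule.isAlgebraic():
            raise UnsupportedSBMLFeatureError("algebraic-rule")
        if rule.isRate():
            raise UnsupportedSBMLFeatureError("rate-rule", rule.getVariable())
    for i in range(model.getNumReactions()):
        kl = model.getReaction(i).getKineticLaw()
        if kl is not None and _ast_uses_delay(kl.getMath()):
            raise UnsupportedSBMLFeatureError("delay", model.getReaction(i).getId())
    doc = model.getSBMLDocument()
    if doc is not None:
        for i in range(doc.getNumPlugins()):
            name = doc.getPlugin(i).getPackageName()
            # the extended-math plugin is part of core L3V2, not a package
            if name != "l3v2extendedmath":
                raise UnsupportedSBMLFeatureError("package", name)


def parse_sbml(document: str) -> ModelSpec:
    """Parse SBML text (or a path to an .xml file) into a flattened-ready
    :class:`ModelSpec`.

    Function definitions are inlined into kinetic laws; local parameters are
    promoted to global scope under the name ``<reaction id>__<param id>``.
    Assignment rules and initial assignments are retained symbolically (they
    are resolved by :func:`flatten_model`).
    """
    if document.lstrip().startswith("<"):
        doc = libsbml.readSBMLFromString(document)
    else:
        doc = libsbml.readSBMLFromFile(document)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise KinfitError(f"SBML read error: {err.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise KinfitError("document contains no model")
    _check_unsupported(model)
    symtab = _collect_symbols(model)

    # capture function definitions before inlining them
    function_defs: dict[str, tuple[tuple[str, ...], sympy.Expr]] = {}
    for i in range(model.getNumFunctionDefinitions()):
        fd = model.getFunctionDefinition(i)
        args = tuple(
            libsbml.formulaToL3String(fd.getMath().getChild(j))
            for j in range(fd.getMath().getNumChildren() - 1)
        )
        arg_syms = dict(symtab)
        arg_syms.update({a: sympy.Symbol(a) for a in args})
        body = _math_to_expr(
            fd.getBody(), where=f"functionDefinition '{fd.getId()}'", symbols=arg_syms
        )
        function_defs[fd.getId()] = (args, body)

    if model.getNumFunctionDefinitions() > 0:
        props = libsbml.ConversionProperties()
        props.addOption("expandFunctionDefinitions", True)
        if doc.convert(props) != libsbml.LIBSBML_OPERATION_SUCCESS:
            raise KinfitError("failed to inline function definitions")
        model = doc.getModel()

    compartments: dict[str, float] = {}
    for i in range(model.getNumCompartments()):
        c = model.getCompartment(i)
        size = c.getSize()
        compartments[c.getId()] = float(size) if math.isfinite(size) else 1.0

    species: list[Species] = []
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        comp = s.getCompartment()
        if s.isSetInitialConcentration():
            value = float(s.getInitialConcentration())
        elif s.isSetInitialAmount():
            value = float(s.getInitialAmount()) / compartments.get(comp, 1.0)
        else:
            value = 0.0
        species.append(
            Species(
                id=s.getId(),
                initial_value=value,
                compartment=comp,
                constant=bool(s.getConstant() or s.getBoundaryCondition()),
            )
        )

    global_params: dict[str, float] = {}
    for i in range(model.getNumParameters()):
        p = model.getParameter(i)
        global_params[p.getId()] = float(p.getValue()) if p.isSetValue() else math.nan

    reactions: list[Reaction] = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        rid = rxn.getId() or f"reaction_{i}"
        reactants = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            st = ref.getStoichiometry()
            reactants[ref.getSpecies()] = reactants.get(ref.getSpecies(), 0.0) + (
                float(st) if math.isfinite(st) else 1.0
            )
        products = {}
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            st = ref.getStoichiometry()
            products[ref.getSpecies()] = products.get(ref.getSpecies(), 0.0) + (
                float(st) if math.isfinite(st) else 1.0
            )
        modifiers = tuple(rxn.getModifier(j).getSpecies() for j in range(rxn.getNumModifiers()))

        kl = rxn.getKineticLaw()
        if kl is None:
            raise KinfitError(f"reaction '{rid}' has no kinetic law")
        rate = _math_to_expr(kl.getMath(), where=f"reaction '{rid}'", symbols=symtab)
        # namespace local parameters: <rid>__<pid>
        n_local = (
            kl.getNumLocalParameters() if kl.getNumLocalParameters() else kl.getNumParameters()
        )
        renames = {}
        for j in range(n_local):
            lp = kl.getLocalParameter(j) or kl.getParameter(j)
            new_id = f"{rid}__{lp.getId()}"
            renames[sympy.Symbol(lp.getId())] = sympy.Symbol(new_id)
            global_params[new_id] = float(lp.getValue()) if lp.isSetValue() else math.nan
        if renames:
            rate = rate.xreplace(renames)
        reactions.append(
            Reaction(id=rid, reactants=reactants, products=products, modifiers=modifiers, rate=rate)
        )

    assignment_rules: dict[str, sympy.Expr] = {}
    for i in range(model.getNumRules()):
        rule = model.getRule(i)
        assignment_rules[rule.getVariable()] = _math_to_expr(
            rule.getMath(), where=f"assignmentRule '{rule.getVariable()}'", symbols=symtab
        )

    initial_assignments: dict[str, sympy.Expr] = {}
    for i in range(model.getNumInitialAssignments()):
        ia = model.getInitialAssignment(i)
        initial_assignments[ia.getSymbol()] = _math_to_expr(
            ia.getMath(), where=f"initialAssignment '{ia.getSymbol()}'", symbols=symtab
        )

    spec = ModelSpec(
        species=species,
        compartments=compartments,
        global_params=global_params,
        reactions=reactions,
        assignment_rules=assignment_rules,
        initial_assignments=initial_assignments,
        function_defs=function_defs,
        model_id=model.getId() or "model",
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# flattening
# ---------------------------------------------------------------------------


def _resolve_rules(rules: dict[str, sympy.Expr]) -> dict[str, sympy.Expr]:
    """Substitute assignment rules into each other to fixpoint."""
    resolved = dict(rules)
    targets = {sympy.Symbol(t) for t in rules}
    for _ in range(len(rules) + 1):
        subs = {sympy.Symbol(t): e for t, e in resolved.items()}
        nxt = {t: e.xreplace(subs) for t, e in resolved.items()}
        if nxt == resolved:
            return resolved
        resolved = nxt
    # still changing after n+1 passes -> cycle
    for t, e in resolved.items():
        if e.free_symbols & targets:
            raise CyclicRuleError(f"assignment rules form a cycle involving '{t}'")
    raise CyclicRuleError("assignment rules form a cycle")


def flatten_model(spec: ModelSpec) -> ModelSpec:
    """Resolve rules, initial assignments and constant species.

    After flattening every rate expression references only dynamic species,
    global parameters, and time; initial assignments have been applied to
    initial values; constant/boundary species appear as numeric constants.
    """
    rules = _resolve_rules(spec.assignment_rules)

    # numeric environment for initial-assignment evaluation
    env: dict[sympy.Symbol, float] = {sympy.Symbol(k): v for k, v in spec.compartments.items()}
    env.update({sympy.Symbol(k): v for k, v in spec.global_params.items()})
    env.update({sympy.Symbol(s.id): s.initial_value for s in spec.species})
    env[TIME] = 0.0

    global_params = dict(spec.global_params)
    species = list(spec.species)
    for target, expr in spec.initial_assignments.items():
        value = expr.xreplace({sympy.Symbol(t): e for t, e in rules.items()}).xreplace(env)
        value = float(sympy.N(value))
        if target in global_params:
            global_params[target] = value
            env[sympy.Symbol(target)] = value
        else:
            for idx, s in enumerate(species):
                if s.id == target:
                    species[idx] = replace(s, initial_value=value)
                    env[sympy.Symbol(target)] = value
                    break
            else:
                raise UnresolvedSymbolError(target, where="initialAssignment")

    # substitution map applied to every rate expression
    sub: dict[sympy.Symbol, sympy.Expr] = {sympy.Symbol(t): e for t, e in rules.items()}
    sub.update({sympy.Symbol(cid): sympy.Float(v) for cid, v in spec.compartments.items()})
    for s in species:
        if s.constant:
            sub[sympy.Symbol(s.id)] = sympy.Float(s.initial_value)
    # rules may themselves reference compartments/constant species
    sub = {k: v.xreplace(sub) if isinstance(v, sympy.Expr) else v for k, v in sub.items()}

    reactions = [replace(r, rate=r.rate.xreplace(sub)) for r in spec.reactions]

    flat = ModelSpec(
        species=species,
        compartments=dict(spec.compartments),
        global_params=global_params,
        reactions=reactions,
        assignment_rules={},
        initial_assignments={},
        function_defs=dict(spec.function_defs),
        model_id=spec.model_id,
        flattened=True,
    )
    # post-flatten check: every remaining free symbol is a dynamic species,
    # a parameter, or time
    allowed = {s.id for s in flat.dynamic_species} | set(flat.global_params) | {str(TIME)}
    for r in flat.reactions:
        for sym in r.rate.free_symbols:
            if str(sym) not in allowed:
                raise UnresolvedSymbolError(str(sym), where=f"reaction '{r.id}' after flattening")
    return flat


def build_stoichiometric_matrix(spec: ModelSpec):
    """Stoichiometric matrix S, shape (n dynamic species, n reactions).

    ``S[i, j]`` is the net production coefficient of dynamic species *i* in
    reaction *j*; modifiers contribute zero.  Rows follow the canonical
    (document) order of dynamic species, columns the document reaction order.
    """
    import numpy as np

    dyn = [s.id for s in spec.dynamic_species]
    S = np.zeros((len(dyn), len(spec.reactions)))
    for j, r in enumerate(spec.reactions):
        for i, sid in enumerate(dyn):
            S[i, j] = r.net_stoichiometry(sid)
    return S


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


class _L3Printer(sympy.printing.str.StrPrinter):
    """Print sympy expressions in libsbml L3-formula syntax."""

    def _print_Pow(self, expr):  # ** -> ^
        return super()._print_Pow(expr).replace("**", "^")

    def _print_log(self, expr):
        if len(expr.args) == 1:
            return f"ln({self._print(expr.args[0])})"
        return super()._print_log(expr)

    def _print_Float(self, expr):
        # shortest repr that round-trips binary64 exactly
        return repr(float(expr))


def _expr_to_ast(expr: sympy.Expr):
    # full_prec so that float constants survive the text round trip exactly
    formula = _L3Printer({"full_prec": True}).doprint(expr).replace("**", "^")
    ast = libsbml.parseL3Formula(formula)
    if ast is None:
        raise KinfitError(f"cannot serialize expression '{formula}' to MathML")
    return ast


def export_sbml(spec: ModelSpec, theta: dict[str, float] | None = None) -> str:
    """Serialize a :class:`ModelSpec` to SBML L3V2 text.

    ``theta`` overrides values of (global) parameters; an unknown id raises
    :class:`~kinfit.errors.UnknownParameterError`.  Local parameters that
    were namespaced at parse time are written back as global parameters.
    """
    theta = dict(theta or {})
    for pid in theta:
        if pid not in spec.global_params:
            raise UnknownParameterError(f"unknown-parameter: '{pid}'")

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId(spec.model_id)

    for cid, size in spec.compartments.items():
        c = model.createCompartment()
        c.setId(cid)
        c.setSize(size)
        c.setConstant(True)
        c.setSpatialDimensions(3)

    for s in spec.species:
        sp = model.createSpecies()
        sp.setId(s.id)
        sp.setCompartment(s.compartment)
        sp.setInitialConcentration(s.initial_value)
        sp.setConstant(bool(s.constant))
        sp.setBoundaryCondition(bool(s.constant))
        sp.setHasOnlySubstanceUnits(False)

    for pid, value in spec.global_params.items():
        p = model.createParameter()
        p.setId(pid)
        p.setValue(theta.get(pid, value))
        p.setConstant(True)

    for target, expr in spec.assignment_rules.items():
        rule = model.createAssignmentRule()
        rule.setVariable(target)
        rule.setMath(_expr_to_ast(expr))

    for target, expr in spec.initial_assignments.items():
        ia = model.createInitialAssignment()
        ia.setSymbol(target)
        ia.setMath(_expr_to_ast(expr))

    for r in spec.reactions:
        rxn = model.createReaction()
        rxn.setId(r.id)
        rxn.setReversible(True)
        for sid, coeff in r.reactants.items():
            ref = rxn.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(coeff)
            ref.setConstant(True)
        for sid, coeff in r.products.items():
            ref = rxn.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(coeff)
            ref.setConstant(True)
        for sid in r.modifiers:
            ref = rxn.createModifier()
            ref.setSpecies(sid)
        kl = rxn.createKineticLaw()
        kl.setMath(_expr_to_ast(r.rate))

    return libsbml.writeSBMLToString(doc)
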