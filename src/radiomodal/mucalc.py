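"""A modal mu-calculus dialect: parser, fixpoint model checker, localization.

The logic is the fragment actually used by the shipped disease property:

* ``tt`` / ``ff`` — true / false;
* ``<a, b> φ`` — some transition labelled with an action *in* the set leads
  to a state satisfying φ (existential diamond over a listed set);
* ``<- a, b> φ`` — some transition labelled with an action *not in* the set
  leads to φ; ``<->`` (empty exclusion) means "some transition";
* ``[-] φ`` — every transition leads to φ; in particular ``[-]ff``
  characterizes deadlock states;
* ``φ ∨ ψ`` — disjunction (``\\/`` in ASCII);
* ``min X = φ`` — least fixpoint, evaluated by Knaster–Tarski iteration
  from the empty set;
* named property references (``F0``–``F14``) — acyclic macros, expanded at
  evaluation time, each closed on its own.

Greatest fixpoints, conjunction and negation are rejected with an explicit
"unsupported" error: the property language deliberately mirrors what the
diagnosis properties need, nothing more.  Both ``∨`` and ``\\/`` are
accepted, as are ``<->``, ``< - >`` and the Unicode minus; fixpoint-variable
lookup is case-insensitive (``min x = ... ∨ <->X`` binds the same variable).

The checker returns the satisfying state set of any formula on a finite LTS,
a true/false verdict for a patient model, a witness action path when the
verdict is true, a furthest-progress note when it is false, and the slice
localization of each named sub-property.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .ccs import Lts
from .errors import ParseError, PropertyError

# ---------------------------------------------------------------------------
# Abstract syntax


class Formula:
    """Base class of all formula nodes."""

    __slots__ = ()


@dataclass(frozen=True)
class TT(Formula):
    pass


@dataclass(frozen=True)
class FF(Formula):
    pass


@dataclass(frozen=True)
class Var(Formula):
    name: str


@dataclass(frozen=True)
class PropRef(Formula):
    name: str


@dataclass(frozen=True)
class Diamond(Formula):
    actions: frozenset[str]
    body: Formula

    def __post_init__(self):
        if not self.actions:
            raise ValueError("diamond action set must be non-empty")


@dataclass(frozen=True)
class DiamondComplement(Formula):
    """Existential step via any action outside ``excluded`` (``<->`` if empty)."""

    excluded: frozenset[str]
    body: Formula


@dataclass(frozen=True)
class BoxAll(Formula):
    body: Formula


@dataclass(frozen=True)
class Or(Formula):
    left: Formula
    right: Formula


@dataclass(frozen=True)
class Min(Formula):
    var: str
    body: Formula


@dataclass(frozen=True)
class PropertySet:
    """Named property definitions with an entry point (default ``F0``)."""

    definitions: Mapping[str, Formula]
    entry: str = "F0"

    def __post_init__(self):
        if self.entry not in self.definitions:
            raise PropertyError(f"entry property {self.entry!r} is not defined")
        _check_refs(self.definitions)

    def __getitem__(self, name: str) -> Formula:
        return self.definitions[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.definitions)

    def depth_order(self) -> dict[str, int]:
        """Longest-path depth of each name in the reference DAG (entry at 0)."""
        refs = {n: _collect_refs(f) for n, f in self.definitions.items()}
        depth = {n: 0 for n in self.definitions}

        def visit(name: str, d: int) -> None:
            if d > depth[name]:
                depth[name] = d
            for r in refs[name]:
                visit(r, d + 1)

        visit(self.entry, 0)
        return depth


def _collect_refs(f: Formula) -> set[str]:
    if isinstance(f, PropRef):
        return {f.name}
    if isinstance(f, (Diamond, DiamondComplement, BoxAll, Min)):
        return _collect_refs(f.body)
    if isinstance(f, Or):
        return _collect_refs(f.left) | _collect_refs(f.right)
    return set()


def _check_refs(definitions: Mapping[str, Formula]) -> None:
    refs = {n: _collect_refs(f) for n, f in definitions.items()}
    for name, rs in refs.items():
        undefined = rs - set(definitions)
        if undefined:
            raise PropertyError(
                f"{name} references undefined property/unbound variable "
                f"{sorted(undefined)[0]!r}"
            )
    # DFS cycle detection over the macro graph
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {n: WHITE for n in definitions}

    def visit(n: str, trail: list[str]) -> None:
        if color[n] == GRAY:
            cycle = " -> ".join(trail[trail.index(n):] + [n])
            raise PropertyError(f"cyclic property references: {cycle}")
        if color[n] == BLACK:
            return
        color[n] = GRAY
        for r in refs[n]:
            visit(r, trail + [n])
        color[n] = BLACK

    for n in definitions:
        visit(n, [])


# ---------------------------------------------------------------------------
# Concrete syntax

_TOKEN_RE = re.compile(r"\\/|/\\|[A-Za-z_][A-Za-z0-9_]*|[=()<>\[\],\-~]|\S")
_KEYWORDS = {"prop", "min", "max", "tt", "ff"}


@dataclass(frozen=True)
class _Token:
    text: str
    line: int
    column: int


def _tokenize(text: str) -> list[_Token]:
    # normalize the typography seen in printed property tables
    text = (
        text.replace("∨", "\\/")  # ∨
        .replace("−", "-")  # minus sign
        .replace(" ", " ")
    )
    tokens = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0]
        for m in _TOKEN_RE.finditer(line):
            tokens.append(_Token(m.group(0), lineno, m.start() + 1))
    return tokens


class _Parser:
    def __init__(self, tokens: list[_Token]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> _Token | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            last = self.tokens[-1] if self.tokens else _Token("", 1, 1)
            raise ParseError("unexpected end of input", last.line, last.column)
        self.pos += 1
        return tok

    def expect(self, text: str) -> _Token:
        tok = self.next()
        if tok.text != text:
            raise ParseError(f"expected {text!r}, found {tok.text!r}", tok.line, tok.column)
        return tok

    def _name(self) -> _Token:
        tok = self.next()
        if not re.match(r"^[A-Za-z_][A-Za-z0-9_]*$", tok.text) or tok.text in _KEYWORDS:
            raise ParseError(f"expected a name, found {tok.text!r}", tok.line, tok.column)
        return tok

    # grammar ---------------------------------------------------------------

    def parse_file(self) -> dict[str, Formula]:
        defs: dict[str, Formula] = {}
        while self.peek() is not None:
            self.expect("prop")
            name = self._name()
            if name.text in defs:
                raise ParseError(
                    f"duplicate property {name.text!r}", name.line, name.column
                )
            self.expect("=")
            defs[name.text] = self.parse_expr([])
        return defs

    def parse_expr(self, bound: list[str]) -> Formula:
        left = self.parse_chain(bound)
        while True:
            tok = self.peek()
            if tok is not None and tok.text == "/\\":
                raise ParseError(
                    "conjunction and negation are unsupported in this dialect",
                    tok.line,
                    tok.column,
                )
            if tok is None or tok.text != "\\/":
                return left
            self.next()
            left = Or(left, self.parse_chain(bound))

    def parse_chain(self, bound: list[str]) -> Formula:
        tok = self.peek()
        if tok is None:
            raise ParseError("formula expected", 1, 1)
        if tok.text == "<":
            self.next()
            nxt = self.peek()
            if nxt is not None and nxt.text == "-":
                self.next()
                excluded = self._action_list(optional=True)
                self.expect(">")
                return DiamondComplement(frozenset(excluded), self.parse_chain(bound))
            actions = self._action_list(optional=False)
            self.expect(">")
            return Diamond(frozenset(actions), self.parse_chain(bound))
        if tok.text == "[":
            self.next()
            self.expect("-")
            self.expect("]")
            return BoxAll(self.parse_chain(bound))
        if tok.text == "(":
            self.next()
            nxt = self.peek()
            if nxt is not None and nxt.text == "min":
                self.next()
                var = self._name()
                self.expect("=")
                body = self.parse_expr(bound + [var.text])
                self.expect(")")
                return Min(var.text, body)
            inner = self.parse_expr(bound)
            self.expect(")")
            return inner
        if tok.text == "tt":
            self.next()
            return TT()
        if tok.text == "ff":
            self.next()
            return FF()
        if tok.text == "max":
            raise ParseError(
                "greatest fixpoints ('max') are unsupported in this dialect",
                tok.line,
                tok.column,
            )
        if tok.text in ("/\\", "~"):
            raise ParseError(
                "conjunction and negation are unsupported in this dialect",
                tok.line,
                tok.column,
            )
        if re.match(r"^[A-Za-z_][A-Za-z0-9_]*$", tok.text) and tok.text not in _KEYWORDS:
            self.next()
            for binder in reversed(bound):  # innermost binder wins
                if binder.lower() == tok.text.lower():
                    return Var(binder)
            return PropRef(tok.text)
        raise ParseError(f"unexpected token {tok.text!r}", tok.line, tok.column)

    def _action_list(self, optional: bool) -> list[str]:
        actions: list[str] = []
        tok = self.peek()
        if tok is not None and tok.text == ">":
            if optional:
                return actions
            raise ParseError("empty action set", tok.line, tok.column)
        actions.append(self._name().text)
        while True:
            tok = self.peek()
            if tok is None or tok.text != ",":
                return actions
            self.next()
            actions.append(self._name().text)


def parse_properties(text: str, entry: str = "F0") -> PropertySet:
    """Parse a property file into a validated :class:`PropertySet`."""
    defs = _Parser(_tokenize(text)).parse_file()
    if not defs:
        raise PropertyError("property file defines no properties")
    if entry not in defs:
        entry = next(iter(defs))
    return PropertySet(defs, entry)


def parse_formula(text: str) -> Formula:
    """Parse a single bare formula (convenience for tests and interactive use)."""
    parser = _Parser(_tokenize(text))
    f = parser.parse_expr([])
    tok = parser.peek()
    if tok is not None:
        raise ParseError(f"trailing input {tok.text!r}", tok.line, tok.column)
    return f


def write_formula(f: Formula) -> str:
    """Serialize a formula back to the ASCII concrete syntax."""
    if isinstance(f, TT):
        return "tt"
    if isinstance(f, FF):
        return "ff"
    if isinstance(f, (Var, PropRef)):
        return f.name
    if isinstance(f, Diamond):
        return f"<{', '.join(sorted(f.actions))}> " + _write_operand(f.body)
    if isinstance(f, DiamondComplement):
        inner = ", ".join(sorted(f.excluded))
        head = f"<- {inner}>" if inner else "<->"
        return head + " " + _write_operand(f.body)
    if isinstance(f, BoxAll):
        return "[-] " + _write_operand(f.body)
    if isinstance(f, Or):
        return write_formula(f.left) + " \\/ " + write_formula(f.right)
    if isinstance(f, Min):
        return f"(min {f.var} = {write_formula(f.body)})"
    raise TypeError(f"unknown formula node {f!r}")


def _write_operand(f: Formula) -> str:
    return f"({write_formula(f)})" if isinstance(f, Or) else write_formula(f)


def write_properties(props: PropertySet) -> str:
    return "\n".join(
        f"prop {name} = {write_formula(f)}" for name, f in props.definitions.items()
    ) + "\n"


# ---------------------------------------------------------------------------
# Semantics: least-fixpoint labelling


def satisfying_states(
    lts: Lts,
    f: Formula,
    props: PropertySet | None = None,
    env: Mapping[str, frozenset[int]] | None = None,
) -> frozenset[int]:
    """States of ``lts`` satisfying ``f`` under ``env`` (standard semantics).

    ``min X = φ`` is computed by Knaster–Tarski iteration from the empty set;
    on a finite LTS the chain stabilizes after at most ``n_states + 1`` steps.
    Named references are expanded through ``props`` (each named property is a
    closed formula, so its satisfying set is cached per call).
    """
    return _Evaluator(lts, props).eval(f, dict(env or {}))


class _Evaluator:
    def __init__(self, lts: Lts, props: PropertySet | None):
        self.lts = lts
        self.props = props
        self._prop_cache: dict[str, frozenset[int]] = {}

    def eval(self, f: Formula, env: dict[str, frozenset[int]]) -> frozenset[int]:
        lts = self.lts
        if isinstance(f, TT):
            return frozenset(lts.states)
        if isinstance(f, FF):
            return frozenset()
        if isinstance(f, Var):
            if f.name not in env:
                raise PropertyError(f"unbound fixpoint variable {f.name!r}")
            return env[f.name]
        if isinstance(f, PropRef):
            if self.props is None:
                raise PropertyError(f"no property set supplied for reference {f.name!r}")
            if f.name not in self._prop_cache:
                self._prop_cache[f.name] = self.eval(self.props[f.name], {})
            return self._prop_cache[f.name]
        if isinstance(f, Diamond):
            body = self.eval(f.body, env)
            return frozenset(
                s
                for s in lts.states
                if any(a in f.actions and t in body for a, t in lts.successors(s))
            )
        if isinstance(f, DiamondComplement):
            body = self.eval(f.body, env)
            return frozenset(
                s
                for s in lts.states
                if any(a not in f.excluded and t in body for a, t in lts.successors(s))
            )
        if isinstance(f, BoxAll):
            body = self.eval(f.body, env)
            # deadlock states satisfy any box vacuously
            return frozenset(
                s for s in lts.states if all(t in body for _, t in lts.successors(s))
            )
        if isinstance(f, Or):
            return self.eval(f.left, env) | self.eval(f.right, env)
        if isinstance(f, Min):
            return self.min_stages(f, env)[-1]
        raise TypeError(f"unknown formula node {f!r}")

    def min_stages(
        self, f: Min, env: dict[str, frozenset[int]]
    ) -> list[frozenset[int]]:
        """The Knaster–Tarski iteration sequence ∅ ⊆ S₁ ⊆ … of a least fixpoint."""
        stages = [frozenset()]
        while True:
            env2 = dict(env)
            env2[f.var] = stages[-1]
            nxt = self.eval(f.body, env2)
            if nxt == stages[-1]:
                return stages
            stages.append(nxt)


def property_sat_sets(lts: Lts, props: PropertySet) -> dict[str, frozenset[int]]:
    """Satisfying state set of every named property on ``lts``."""
    ev = _Evaluator(lts, props)
    return {name: ev.eval(PropRef(name), {}) for name in props.names}


# ---------------------------------------------------------------------------
# Verdicts, witnesses, localization


@dataclass(frozen=True)
class CheckResult:
    """Outcome of checking one patient model against a property set."""

    verdict: bool
    sat_sets: Mapping[str, frozenset[int]]
    witness: tuple[str, ...] | None
    failure: str | None

    def to_dict(self, lts: Lts | None = None) -> dict:
        doc = {
            "verdict": self.verdict,
            "witness": list(self.witness) if self.witness is not None else None,
            "failure": self.failure,
        }
        if lts is not None and lts.slice_of is not None:
            doc["slices"] = {
                name: sorted({lts.state_slice(s) for s in states})
                for name, states in self.sat_sets.items()
            }
        return doc


def check_patient(lts: Lts, props: PropertySet) -> CheckResult:
    """True/false verdict of the entry property at the initial state.

    A true verdict carries a witness action path consistent with the diamond
    obligations that were discharged; a false verdict carries a note naming
    the sub-property whose obligations advanced furthest along the chain and
    the slice where progress stopped.
    """
    sat = property_sat_sets(lts, props)
    verdict = 0 in sat[props.entry]
    if verdict:
        witness = tuple(_witness(lts, props, PropRef(props.entry), 0, {}))
        return CheckResult(True, sat, witness, None)
    return CheckResult(False, sat, None, _failure_note(lts, props, sat))


def localize(
    lts: Lts, props: PropertySet, names: Sequence[str] | None = None
) -> dict[str, set[int]]:
    """Slice indices owning at least one satisfying state, per property name."""
    names = list(props.names) if names is None else list(names)
    unknown = set(names) - set(props.names)
    if unknown:
        raise PropertyError(f"unknown property name {sorted(unknown)[0]!r}")
    sat = property_sat_sets(lts, props)
    return {
        name: {lts.state_slice(s) for s in sat[name]} for name in names
    }


@dataclass(frozen=True)
class _MinCtx:
    formula: Min
    stages: tuple[frozenset[int], ...]
    env: tuple  # frozen items of the enclosing witness env
    bound: int  # Var occurrences may only use stages up to this index


def _witness(
    lts: Lts,
    props: PropertySet | None,
    f: Formula,
    state: int,
    env: dict[str, _MinCtx],
) -> list[str]:
    """Reconstruct one action path discharging the diamond obligations of ``f``.

    Fixpoint unfoldings are rank-restricted (a variable occurrence may only
    appeal to strictly earlier iteration stages), which makes the recursion
    well-founded on any finite LTS.
    """
    ev = _Evaluator(lts, props)

    def sets_env(e: dict[str, _MinCtx]) -> dict[str, frozenset[int]]:
        return {name: ctx.stages[ctx.bound] for name, ctx in e.items()}

    def go(f: Formula, s: int, e: dict[str, _MinCtx]) -> list[str]:
        if isinstance(f, (TT, FF)):
            return []
        if isinstance(f, PropRef):
            return go(props[f.name], s, {})
        if isinstance(f, Or):
            if s in ev.eval(f.left, sets_env(e)):
                return go(f.left, s, e)
            return go(f.right, s, e)
        if isinstance(f, Diamond):
            body = ev.eval(f.body, sets_env(e))
            for a, t in lts.successors(s):
                if a in f.actions and t in body:
                    return [a] + go(f.body, t, e)
            raise PropertyError("witness reconstruction failed (diamond)")
        if isinstance(f, DiamondComplement):
            body = ev.eval(f.body, sets_env(e))
            for a, t in lts.successors(s):
                if a not in f.excluded and t in body:
                    return [a] + go(f.body, t, e)
            raise PropertyError("witness reconstruction failed (complement diamond)")
        if isinstance(f, BoxAll):
            return []  # universal obligations contribute no witness actions
        if isinstance(f, Min):
            stages = tuple(ev.min_stages(f, sets_env(e)))
            rank = next(i for i, st in enumerate(stages) if s in st)
            e2 = dict(e)
            e2[f.var] = _MinCtx(f, stages, tuple(e.items()), rank - 1)
            return go(f.body, s, e2)
        if isinstance(f, Var):
            ctx = e[f.name]
            rank = next(
                i for i in range(ctx.bound + 1) if s in ctx.stages[i]
            )
            # re-enter the binder's scope with a strictly tightened stage bound
            e2 = dict(ctx.env)
            e2[f.name] = _MinCtx(ctx.formula, ctx.stages, ctx.env, rank - 1)
            return go(ctx.formula.body, s, e2)
        raise TypeError(f"unknown formula node {f!r}")

    return go(f, state, env)


def _failure_note(
    lts: Lts, props: PropertySet, sat: Mapping[str, frozenset[int]]
) -> str:
    depth = props.depth_order()
    nonempty = [n for n in props.names if sat[n]]
    if not nonempty:
        return (
            f"{props.entry} fails: no sub-property holds anywhere; "
            "obligations never start"
        )
    deepest = max(nonempty, key=lambda n: (depth[n], list(props.names).index(n)))
    last_state = max(sat[deepest])
    where = (
        f"slice {lts.state_slice(last_state)}"
        if lts.slice_of is not None
        else f"state {last_state}"
    )
    return (
        f"{props.entry} fails at the initial state; furthest progress in "
        f"{deepest} (deepest sub-property satisfied), last satisfied at {where}"
    )


# ---------------------------------------------------------------------------
# The bundled diagnosis property

#: Disease property shipped with the package: two alternative patterns over
#: the discretized features — a sphericity/kurtosis chain (F1–F4) requiring
#: four high-sphericity/low-kurtosis consecutive pairs, the last two reached
#: without crossing stray occurrences of those actions, and a
#: sphericity/kurtosis/meshsurface/elongation chain (F10–F14) ending in a
#: basal meshsurface-or-elongation action immediately before termination.
DIAGNOSIS_PROPERTY_TEXT = """\
prop F0 = F1 \\/ F10
prop F1 = (min X = <b3of3sphericity> <b1of3kurtosis> F2 \\/ <-> X)
prop F2 = (min X = <b3of3sphericity> <b1of3kurtosis> F3 \\/ <-> X)
prop F3 = (min X = <b3of3sphericity> <b1of3kurtosis> F4 \\/ <- b3of3sphericity, b1of3kurtosis> X)
prop F4 = (min X = <b3of3sphericity> <b1of3kurtosis> tt \\/ <- b3of3sphericity, b1of3kurtosis> X)
prop F10 = (min X = <b3of3sphericity> <b1of3kurtosis, b2of3kurtosis> <b3of3meshsurface, b3of3elongation> F11 \\/ <-> X)
prop F11 = (min X = <b3of3sphericity> <b1of3kurtosis, b2of3kurtosis> <b3of3meshsurface, b2of3meshsurface> F12 \\/ <-> X)
prop F12 = (min X = <b3of3sphericity> <b1of3kurtosis, b2of3kurtosis> <b3of3meshsurface, b3of3elongation> F13 \\/ <-> X)
prop F13 = (min X = <b3of3sphericity> <b1of3kurtosis, b2of3kurtosis> <b3of3elongation, b3of3meshsurface> F14 \\/ <-> X)
prop F14 = (min X = <b2of3meshsurface, b2of3elongation> [-] ff \\/ <-> X)
"""


def diagnosis_properties() -> PropertySet:
    """The bundled diagnosis property set (entry ``F0``)."""
    return parse_properties(DIAGNOSIS_PROPERTY_TEXT, entry="F0")


def read_properties(path: str | Path, entry: str = "F0") -> PropertySet:
    """Read a ``.mcf`` property file (UTF-8; ``∨`` and ``\\/`` both accepted)."""
    return parse_properties(Path(path).read_text(encoding="utf-8"), entry=entry)
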