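"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive and structurally separate from the
shipped evaluator: plain dict/set recursion, no caching, no frozensets, and
(for small systems) least fixpoints obtained straight from the Knaster–Tarski
characterization by enumerating *all* candidate prefixed points.
"""

from __future__ import annotations

from itertools import chain, combinations

import numpy as np

from radiomodal.mucalc import (
    BoxAll,
    Diamond,
    DiamondComplement,
    FF,
    Min,
    Or,
    PropRef,
    TT,
    Var,
)


def bf_eval(
    succ: dict, n: int, f, env: dict, defs: dict | None = None, _cache: dict | None = None
) -> set:
    """Naive semantics; least fixpoints by repeated full re-evaluation.

    Macro references are resolved once per call (they are textual expansion,
    not part of the fixpoint computation under test); everything else is
    recomputed from scratch at every fixpoint iteration.
    """
    if _cache is None:
        _cache = {}
    if isinstance(f, TT):
        return set(range(n))
    if isinstance(f, FF):
        return set()
    if isinstance(f, Var):
        return set(env[f.name])
    if isinstance(f, PropRef):
        if f.name not in _cache:
            _cache[f.name] = bf_eval(succ, n, defs[f.name], {}, defs, _cache)
        return set(_cache[f.name])
    if isinstance(f, Or):
        return bf_eval(succ, n, f.left, env, defs, _cache) | bf_eval(
            succ, n, f.right, env, defs, _cache
        )
    if isinstance(f, (Diamond, DiamondComplement, BoxAll)):
        body = bf_eval(succ, n, f.body, env, defs, _cache)
        result = set()
        for s in range(n):
            succs = succ.get(s, [])
            if isinstance(f, Diamond):
                ok = any(a in f.actions and t in body for a, t in succs)
            elif isinstance(f, DiamondComplement):
                ok = any(a not in f.excluded and t in body for a, t in succs)
            else:
                ok = all(t in body for _, t in succs)
            if ok:
                result.add(s)
        return result
    if isinstance(f, Min):
        current: set = set()
        while True:
            env2 = dict(env)
            env2[f.var] = current
            nxt = bf_eval(succ, n, f.body, env2, defs, _cache)
            if nxt == current:
                return current
            current = nxt
    raise TypeError(f)


def bf_eval_enum(succ: dict, n: int, f, env: dict, defs: dict | None = None) -> set:
    """Semantics with least fixpoints taken as the intersection of all
    prefixed points, enumerated over the full powerset (only viable for tiny
    systems; definitionally independent of any iteration scheme)."""
    if isinstance(f, Min):
        states = list(range(n))
        prefixed = []
        for r in range(n + 1):
            for subset in combinations(states, r):
                cand = set(subset)
                env2 = dict(env)
                env2[f.var] = cand
                if bf_eval_enum(succ, n, f.body, env2, defs) <= cand:
                    prefixed.append(cand)
        out = set(states)
        for p in prefixed:
            out &= p
        return out
    if isinstance(f, Or):
        return bf_eval_enum(succ, n, f.left, env, defs) | bf_eval_enum(
            succ, n, f.right, env, defs
        )
    if isinstance(f, (Diamond, DiamondComplement, BoxAll)):
        body = lambda e: bf_eval_enum(succ, n, f.body, e, defs)
        result = set()
        for s in range(n):
            succs = succ.get(s, [])
            if isinstance(f, Diamond):
                ok = any(a in f.actions and t in body(env) for a, t in succs)
            elif isinstance(f, DiamondComplement):
                ok = any(a not in f.excluded and t in body(env) for a, t in succs)
            else:
                ok = all(t in body(env) for _, t in succs)
            if ok:
                result.add(s)
        return result
    if isinstance(f, PropRef):
        return bf_eval_enum(succ, n, defs[f.name], {}, defs)
    return bf_eval(succ, n, f, env, defs)


def adjacency(lts) -> tuple[dict, int]:
    """Plain-dict successor map of an Lts, for the oracles above."""
    succ: dict[int, list] = {}
    for s, a, t in lts.transitions:
        succ.setdefault(s, []).append((a, t))
    return succ, lts.n_states


def random_chain_actions(rng: np.random.Generator, max_len: int, alphabet) -> list[str]:
    length = int(rng.integers(1, max_len + 1))
    return [alphabet[i] for i in rng.integers(0, len(alphabet), size=length)]


def random_formula(rng: np.random.Generator, depth: int, alphabet, bound=()):
    """A random closed formula of the supported dialect."""
    leaf_kinds = ["tt", "ff"] + (["var"] if bound else [])
    if depth <= 0:
        kind = leaf_kinds[rng.integers(0, len(leaf_kinds))]
    else:
        kinds = ["dia", "ndia", "box", "or", "min"] + leaf_kinds
        kind = kinds[rng.integers(0, len(kinds))]
    if kind == "tt":
        return TT()
    if kind == "ff":
        return FF()
    if kind == "var":
        return Var(bound[int(rng.integers(0, len(bound)))])
    if kind == "dia":
        k = int(rng.integers(1, min(3, len(alphabet)) + 1))
        acts = frozenset(
            alphabet[i] for i in rng.choice(len(alphabet), size=k, replace=False)
        )
        return Diamond(acts, random_formula(rng, depth - 1, alphabet, bound))
    if kind == "ndia":
        k = int(rng.integers(0, min(3, len(alphabet)) + 1))
        acts = frozenset(
            alphabet[i] for i in rng.choice(len(alphabet), size=k, replace=False)
        )
        return DiamondComplement(acts, random_formula(rng, depth - 1, alphabet, bound))
    if kind == "box":
        return BoxAll(random_formula(rng, depth - 1, alphabet, bound))
    if kind == "or":
        return Or(
            random_formula(rng, depth - 1, alphabet, bound),
            random_formula(rng, depth - 1, alphabet, bound),
        )
    var = f"X{len(bound)}"
    return Min(var, random_formula(rng, depth - 1, alphabet, bound + (var,)))


def suffix_scan(actions: list[str], phi_states: set) -> set:
    """States of a chain from which some (possibly current) suffix state is in
    ``phi_states`` — the closed form of ``min X = φ ∨ <->X`` on chains."""
    n = len(actions) + 1
    out = set()
    reachable_hit = False
    for s in range(n - 1, -1, -1):
        if s in phi_states or reachable_hit:
            out.add(s)
            reachable_hit = True
    return out


def rank_with_ties(values) -> np.ndarray:
    """Average ranks computed from first principles (independent of scipy)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks
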