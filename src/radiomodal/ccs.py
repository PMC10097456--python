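"""CCS chain processes and their labelled transition systems.

Each exam becomes one process in the action-prefix fragment of the Calculus
of Communicating Systems: the patient's discretized actions combined with the
``.`` operator and terminated by ``nil``.  Only this fragment is supported —
choice, parallel composition, restriction and relabelling never occur in the
models this pipeline builds.

Concrete syntax (CWB-flavoured), one process per line, ``#`` comments::

    proc STS_038 = b3of3sphericity.b1of3kurtosis. ... .nil

Unfolding a process with ``k`` actions yields a linear chain LTS with states
``0..k``: state ``i`` steps to ``i+1`` on the ``i+1``-th action and the final
state is a deadlock.  State ``i`` belongs to the slice of the action it is
about to consume (``i // 5`` for five actions per slice); the final state
belongs to the last slice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .discretize import ActionSequence, parse_action_label
from .errors import ParseError, RadiomodalError

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def process_name(patient_id: str) -> str:
    """Derive a valid process identifier from a patient id."""
    name = re.sub(r"[^A-Za-z0-9_]", "_", str(patient_id))
    if not name or name[0].isdigit():
        name = "P_" + name
    return name


@dataclass(frozen=True)
class CcsProcess:
    """A nil-terminated prefix process: ``name = a1.a2.....nil``."""

    name: str
    actions: tuple[str, ...]

    def __post_init__(self):
        if not _NAME_RE.match(self.name):
            raise ValueError(f"invalid process name {self.name!r}")
        if not self.actions:
            raise ValueError("process must have at least one action")
        for a in self.actions:
            parse_action_label(a)


def build_process(seq: ActionSequence) -> CcsProcess:
    """Turn a patient's action sequence into its CCS chain process."""
    if not seq.actions:
        raise RadiomodalError("cannot build a process from an empty sequence")
    return CcsProcess(process_name(seq.patient_id), tuple(seq.actions))


def write_ccs(p: CcsProcess) -> str:
    """Serialize one process as a single ``proc`` line."""
    return f"proc {p.name} = " + ".".join(p.actions) + ".nil"


def write_ccs_model(processes: Iterable[CcsProcess]) -> str:
    """Serialize several processes, one per line."""
    return "\n".join(write_ccs(p) for p in processes) + "\n"


def parse_ccs_model(text: str) -> list[CcsProcess]:
    """Parse a ``.ccs`` model file into its processes.

    Accepts blank lines, ``#`` comments and arbitrary whitespace around the
    ``.`` separators; process names must be unique within the file.
    """
    processes: list[CcsProcess] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0]
        if not line.strip():
            continue
        processes.append(_parse_proc_line(line, lineno))
        name = processes[-1].name
        if name in seen:
            raise ParseError(f"duplicate process name {name!r}", lineno, 1)
        seen.add(name)
    return processes


def parse_ccs(text: str) -> CcsProcess:
    """Parse text containing exactly one process definition."""
    procs = parse_ccs_model(text)
    if len(procs) != 1:
        raise ParseError(f"expected exactly one process, found {len(procs)}", 1, 1)
    return procs[0]


def _parse_proc_line(line: str, lineno: int) -> CcsProcess:
    m = re.match(r"\s*proc\s+([A-Za-z_][A-Za-z0-9_]*)\s*=\s*(.*?)\s*$", line)
    if not m:
        col = len(line) - len(line.lstrip()) + 1
        raise ParseError("expected 'proc NAME = body'", lineno, col)
    name, body = m.group(1), m.group(2)
    body_start = m.start(2)
    tokens: list[tuple[str, int]] = []
    for tm in re.finditer(r"[^.\s]+", body):
        tokens.append((tm.group(0), body_start + tm.start() + 1))
    if not tokens or tokens[-1][0] != "nil":
        raise ParseError("process body must end with 'nil'", lineno, len(line))
    actions = []
    for tok, col in tokens[:-1]:
        try:
            parse_action_label(tok)
        except ValueError:
            raise ParseError(f"unknown action token {tok!r}", lineno, col) from None
        actions.append(tok)
    if not actions:
        raise ParseError("process must have at least one action before nil", lineno, 1)
    return CcsProcess(name, tuple(actions))


@dataclass(frozen=True)
class Lts:
    """A finite labelled transition system with initial state 0.

    ``slice_of`` maps a state to its slice index when the LTS came from a
    per-slice action chain (None for ad-hoc systems).
    """

    n_states: int
    transitions: tuple[tuple[int, str, int], ...]
    slice_of: tuple[int, ...] | None = None
    _succ: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        succ: dict[int, list[tuple[str, int]]] = {s: [] for s in range(self.n_states)}
        for src, action, dst in self.transitions:
            if not (0 <= src < self.n_states and 0 <= dst < self.n_states):
                raise ValueError("transition endpoint out of range")
            succ[src].append((action, dst))
        object.__setattr__(self, "_succ", succ)

    @property
    def states(self) -> range:
        return range(self.n_states)

    def successors(self, state: int) -> list[tuple[str, int]]:
        return self._succ[state]

    def state_slice(self, state: int) -> int:
        if self.slice_of is None:
            raise RadiomodalError("this LTS carries no slice map")
        return self.slice_of[state]

    @property
    def actions(self) -> tuple[str, ...]:
        return tuple(a for _, a, _ in self.transitions)


def chain_lts(actions: Sequence[str], actions_per_slice: int | None = 5) -> Lts:
    """Linear chain LTS for an action list (used by :func:`to_lts` and tests)."""
    k = len(actions)
    transitions = tuple((i, a, i + 1) for i, a in enumerate(actions))
    slice_of = None
    if actions_per_slice:
        # state i consumes action i next; the deadlock state stays on the last slice
        slice_of = tuple(min(i, k - 1) // actions_per_slice for i in range(k + 1))
    return Lts(k + 1, transitions, slice_of)


def to_lts(p: CcsProcess, actions_per_slice: int = 5) -> Lts:
    """Unfold a prefix process into its chain LTS with the slice map."""
    return chain_lts(p.actions, actions_per_slice)
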