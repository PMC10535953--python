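"""SMILES tokenization and molecular-feature extraction.

A molecule enters the model as a plain SMILES string.  Two families of
features carry correlation weights:

* **SMILES attributes** — single tokens ("SMILES atoms": one line symbol,
  a two-letter element, a bracket-atom block, or a ``%nn`` ring label) and
  canonicalized pairs of adjacent tokens.
* **Graph invariants** — per-vertex Morgan extended-connectivity values of
  the hydrogen-suppressed graph (HSG), optionally mixed into the same
  descriptor.

Every feature is named by a fixed-width 12-character code so that weight
tables, promoter reports and applicability-domain bookkeeping all share a
single flat attribute vocabulary.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "SmilesError",
    "tokenize_smiles",
    "atom_code",
    "pair_code",
    "graph_code",
    "attribute_kind",
    "atom_attributes",
    "pair_attributes",
    "MolecularGraph",
    "build_hsg",
    "morgan_ec",
    "graph_attributes",
    "FeatureConfig",
    "extract_features",
]

CODE_WIDTH = 12
FIELD_WIDTH = 4

#: Two-letter element symbols recognised outside brackets.
TWO_LETTER_ELEMENTS = ("Cl", "Br")

#: Bond, branch and disconnection symbols accepted as single tokens.
_SINGLE_SYMBOLS = set("=#/\\()-:.+@")


class SmilesError(ValueError):
    """Raised for malformed SMILES; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into its inseparable symbol groups.

    One token is: a bracket-atom block ``[...]``, a two-digit ring label
    ``%nn``, a two-letter element symbol (Cl, Br), or a single character
    (element, aromatic atom, ring digit, bond or branch symbol).
    Concatenating the tokens reproduces the input exactly.

    Raises
    ------
    SmilesError
        On unbalanced brackets/parentheses, a dangling ``%``, or an
        unmatched ring-closure label.
    """
    if not smiles:
        raise SmilesError("empty SMILES", 0)
    if any(ch.isspace() for ch in smiles):
        raise SmilesError("whitespace in SMILES", smiles.index(" ") if " " in smiles else 0)

    tokens: list[str] = []
    depth = 0
    open_rings: dict[str, int] = {}
    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i + 1)
            if j < 0:
                raise SmilesError("unclosed bracket atom", i)
            if j == i + 1:
                raise SmilesError("empty bracket atom", i)
            tokens.append(smiles[i : j + 1])
            i = j + 1
            continue
        if ch == "]":
            raise SmilesError("unmatched ']'", i)
        if ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise SmilesError("dangling '%' ring label", i)
            label = smiles[i : i + 3]
            _toggle_ring(open_rings, label, i)
            tokens.append(label)
            i += 3
            continue
        if smiles[i : i + 2] in TWO_LETTER_ELEMENTS:
            tokens.append(smiles[i : i + 2])
            i += 2
            continue
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise SmilesError("unbalanced ')'", i)
        elif ch.isdigit():
            _toggle_ring(open_rings, ch, i)
        elif not (ch.isalpha() or ch in _SINGLE_SYMBOLS):
            raise SmilesError(f"unexpected character {ch!r}", i)
        tokens.append(ch)
        i += 1
    if depth != 0:
        raise SmilesError("unbalanced '('", n - 1)
    if open_rings:
        label, pos = next(iter(open_rings.items()))
        raise SmilesError(f"unmatched ring label {label!r}", pos)
    return tokens


def _toggle_ring(open_rings: dict[str, int], label: str, pos: int) -> None:
    if label in open_rings:
        del open_rings[label]
    else:
        open_rings[label] = pos


# ---------------------------------------------------------------------------
# Attribute codes


def _pad(token: str) -> str:
    # Fixed-width field; rare >4-char bracket atoms are truncated.
    return token[:FIELD_WIDTH].ljust(FIELD_WIDTH, ".")


def atom_code(token: str) -> str:
    """12-character code of a single-token attribute, e.g. ``C...........``."""
    return _pad(token).ljust(CODE_WIDTH, ".")


def pair_code(a: str, b: str) -> str:
    """Canonical 12-character code of an adjacent token pair.

    The two fields are ordered descending by raw token text, so
    ``pair_code(x, y) == pair_code(y, x)``; e.g. ('C', 'O') and
    ('O', 'C') both yield ``O...C.......``.
    """
    hi, lo = (a, b) if a >= b else (b, a)
    return (_pad(hi) + _pad(lo)).ljust(CODE_WIDTH, ".")


def graph_code(order: int, element: str, value: int) -> str:
    """Code of a graph invariant: Morgan EC of the given order, e.g. ``EC0-C-2.....``."""
    return f"EC{order}-{element}-{value}".ljust(CODE_WIDTH, ".")


_PAIR_RE = re.compile(r"^.{4}[^.]")


def attribute_kind(code: str) -> str:
    """Classify a code as ``'atom'``, ``'pair'`` or ``'graph'``."""
    if code.startswith("EC") and "-" in code:
        return "graph"
    if _PAIR_RE.match(code):
        return "pair"
    return "atom"


def atom_attributes(tokens: list[str]) -> Counter[str]:
    """One atom-kind code per token occurrence (multiset)."""
    return Counter(atom_code(t) for t in tokens)


def pair_attributes(tokens: list[str]) -> Counter[str]:
    """One canonical pair-kind code per adjacent token pair (multiset).

    The multiset size is exactly ``len(tokens) - 1`` for non-empty input.
    """
    return Counter(pair_code(a, b) for a, b in zip(tokens, tokens[1:]))


# ---------------------------------------------------------------------------
# Hydrogen-suppressed graph


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed molecular graph.

    ``vertices[i]`` is the element symbol of heavy atom *i*; ``edges`` are
    unordered index pairs following SMILES adjacency, branching and
    ring-closure semantics.
    """

    vertices: list[str] = field(default_factory=list)
    edges: list[tuple[int, int]] = field(default_factory=list)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.vertices]
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj


_BRACKET_ELEMENT_RE = re.compile(r"\[(?:\d+)?([A-Za-z][a-z]?)")


def _token_element(token: str) -> str | None:
    """Element symbol of an atom token, or None for a non-atom token."""
    if token.startswith("["):
        m = _BRACKET_ELEMENT_RE.match(token)
        if m is None:
            return None
        sym = m.group(1)
        return sym.capitalize() if sym not in ("H",) else "H"
    if token in TWO_LETTER_ELEMENTS:
        return token
    if len(token) == 1 and token.isalpha():
        # aromatic lowercase maps to its element in the graph
        return token.upper()
    return None


def build_hsg(smiles: str) -> MolecularGraph:
    """Build the hydrogen-suppressed graph from a SMILES string.

    Branches are handled with a stack; each matched pair of ring-closure
    labels contributes exactly one edge.  Aromatic lowercase atoms map to
    their uppercase element.  A '.' disconnection starts a new component.
    """
    tokens = tokenize_smiles(smiles)
    g = MolecularGraph()
    prev: int | None = None
    stack: list[int | None] = []
    ring_open: dict[str, int] = {}
    seen_edges: set[tuple[int, int]] = set()

    def add_edge(a: int, b: int) -> None:
        if a == b:
            raise SmilesError("ring closure produces a self-loop", 0)
        key = (min(a, b), max(a, b))
        if key not in seen_edges:
            seen_edges.add(key)
            g.edges.append(key)

    for tok in tokens:
        el = _token_element(tok)
        if el is not None:
            if el == "H":
                continue  # explicit [H]: suppressed
            idx = len(g.vertices)
            g.vertices.append(el)
            if prev is not None:
                add_edge(prev, idx)
            prev = idx
        elif tok == "(":
            stack.append(prev)
        elif tok == ")":
            prev = stack.pop()
        elif tok == ".":
            prev = None
        elif tok.isdigit() or tok.startswith("%"):
            if prev is None:
                raise SmilesError("ring label before any atom", 0)
            if tok in ring_open:
                add_edge(ring_open.pop(tok), prev)
            else:
                ring_open[tok] = prev
        # bond/stereo symbols carry no graph information here
    if ring_open:
        raise SmilesError(f"unmatched ring label {next(iter(ring_open))!r}", 0)
    if not g.vertices:
        raise SmilesError("SMILES contains no heavy atom", 0)
    return g


def morgan_ec(graph: MolecularGraph, order: int) -> list[int]:
    """Classical Morgan extended connectivity of each vertex.

    Order 0 is the vertex degree; order *k* sums the neighbours'
    order-(k-1) values.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    adj = graph.adjacency()
    values = [len(nb) for nb in adj]
    for _ in range(order):
        values = [sum(values[j] for j in adj[i]) for i in range(len(adj))]
    return values


def graph_attributes(graph: MolecularGraph, orders: set[int] | frozenset[int]) -> Counter[str]:
    """One graph-kind code per vertex per requested Morgan order."""
    out: Counter[str] = Counter()
    for order in sorted(orders):
        for el, v in zip(graph.vertices, morgan_ec(graph, order)):
            out[graph_code(order, el, v)] += 1
    return out


# ---------------------------------------------------------------------------
# Feature extraction front door


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature classes enter the descriptor.

    Graph invariants are off by default: the plain optimal descriptor sums
    only SMILES-attribute weights; the hybrid adds Morgan-EC invariants of
    the listed orders into the same sum.
    """

    use_atoms: bool = True
    use_pairs: bool = True
    graph_orders: frozenset[int] = frozenset()

    def __post_init__(self):
        if not self.graph_orders <= {0, 1, 2, 3}:
            raise ValueError("graph_orders must be a subset of {0,1,2,3}")


def extract_features(smiles: str, config: FeatureConfig | None = None) -> Counter[str]:
    """Full attribute multiset of one compound under the given configuration."""
    config = config or FeatureConfig()
    tokens = tokenize_smiles(smiles)
    out: Counter[str] = Counter()
    if config.use_atoms:
        out += atom_attributes(tokens)
    if config.use_pairs:
        out += pair_attributes(tokens)
    if config.graph_orders:
        out += graph_attributes(build_hsg(smiles), config.graph_orders)
    return out
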