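"""Self-referencing embedded string (SELFIES-style) codec.

Converts canonical, stereochemistry-free SMILES into a self-delimiting
bracketed-symbol notation and back.  Atoms keep their SMILES spelling
inside brackets (``[C]``, ``[c]``, ``[nH]``, ``[N+]``); non-single bonds
become symbol prefixes (``[=O]``); SMILES parentheses are replaced by
``[BranchK]`` symbols annotating the branch length; ring-closure digit
pairs become ``[RingK]`` symbols that reference how many symbols back the
ring-opening atom lies.  Branch lengths and ring references are written in
base-16 index symbols ``[0]``..``[15]`` (K = number of index symbols,
value = encoded number, meaning length-1 for branches and distance-1 for
rings).

The codec covers stereochemistry-free RDKit canonical SMILES over the
organic subset plus bracket atoms.  Round-trip contract:
``decode(encode(s))`` re-canonicalizes to ``s``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["encode", "decode", "split_symbols", "SelfiesError"]

_INDEX_SYMBOLS = [f"[{i}]" for i in range(16)]
_INDEX_VALUE = {s: i for i, s in enumerate(_INDEX_SYMBOLS)}

_SMILES_TOKEN = re.compile(
    r"\[[^\]]+\]|Br|Cl|%\d{2}|[BCNOPSFI]|[bcnops]|\d|[=#\-:/\\.()]"
)

_BONDS = {"=", "#", "-", ":"}


class SelfiesError(ValueError):
    """Raised for strings outside the codec's grammar."""


def _tokenize(smiles: str) -> list[str]:
    tokens, pos = [], 0
    for m in _SMILES_TOKEN.finditer(smiles):
        if m.start() != pos:
            raise SelfiesError(
                f"unsupported SMILES character at position {pos}: {smiles[pos]!r}")
        tokens.append(m.group())
        pos = m.end()
    if pos != len(smiles):
        raise SelfiesError(
            f"unsupported SMILES character at position {pos}: {smiles[pos]!r}")
    return tokens


# --- parse to an AST ------------------------------------------------------

@dataclass
class _Atom:
    bond: str
    text: str           # SMILES spelling without surrounding brackets
    pos: int = -1       # flattened symbol position (filled during layout)


@dataclass
class _Branch:
    children: list
    k: int = 1          # number of index symbols


@dataclass
class _RingClose:
    bond: str
    opener: _Atom
    k: int = 1
    pos: int = -1


def _parse(tokens: list[str]) -> list:
    """Parse SMILES tokens into a nested node list; pair ring digits."""
    open_rings: dict[str, tuple[_Atom, str]] = {}
    last_atom: list[_Atom | None] = [None]

    def parse_seq(i: int, stop_at_close: bool) -> tuple[list, int]:
        nodes: list = []
        while i < len(tokens):
            tok = tokens[i]
            bond = ""
            if tok in _BONDS:
                bond = tok
                i += 1
                if i >= len(tokens):
                    raise SelfiesError("dangling bond symbol")
                tok = tokens[i]
            if tok == "(":
                children, i = parse_seq(i + 1, True)
                if bond:
                    # bond binds to first atom of the branch
                    first = children[0]
                    if not isinstance(first, _Atom):
                        raise SelfiesError("bond into non-atom branch head")
                    first.bond = bond
                if not children:
                    raise SelfiesError("empty branch")
                nodes.append(_Branch(children))
                continue
            if tok == ")":
                if not stop_at_close:
                    raise SelfiesError("unbalanced parenthesis")
                return nodes, i + 1
            if tok.isdigit() or tok.startswith("%"):
                num = tok.lstrip("%")
                if num in open_rings:
                    opener, open_bond = open_rings.pop(num)
                    nodes.append(_RingClose(bond or open_bond, opener))
                else:
                    if last_atom[0] is None:
                        raise SelfiesError("ring digit before any atom")
                    open_rings[num] = (last_atom[0], bond)
                i += 1
                continue
            if tok == ".":
                raise SelfiesError("disconnected structures not supported")
            atom_text = tok[1:-1] if tok.startswith("[") else tok
            atom = _Atom(bond, atom_text)
            nodes.append(atom)
            last_atom[0] = atom
            i += 1
        if stop_at_close:
            raise SelfiesError("unbalanced parenthesis")
        return nodes, i

    nodes, _ = parse_seq(0, False)
    if open_rings:
        raise SelfiesError(f"unclosed ring bond(s): {sorted(open_rings)}")
    return nodes


def _index_digits(value: int, k: int) -> list[str]:
    digits = []
    for _ in range(k):
        digits.append(_INDEX_SYMBOLS[value % 16])
        value //= 16
    if value:
        raise SelfiesError("index overflow")
    return digits[::-1]


def encode(smiles: str) -> str:
    """Encode a canonical stereochemistry-free SMILES string."""
    if not smiles:
        raise SelfiesError("empty SMILES string")
    root = _parse(_tokenize(smiles))

    def layout(nodes: list, pos: int) -> int:
        """Assign flattened symbol positions; return next free position."""
        for node in nodes:
            if isinstance(node, _Atom):
                node.pos = pos
                pos += 1
            elif isinstance(node, _RingClose):
                node.pos = pos
                pos += 1 + node.k
            else:  # _Branch
                pos = layout(node.children, pos + 1 + node.k)
        return pos

    def widen(nodes: list) -> bool:
        """Grow index-symbol counts where values no longer fit; True if changed."""
        changed = False
        for node in nodes:
            if isinstance(node, _RingClose):
                value = node.pos - node.opener.pos - 1
                while value >= 16**node.k:
                    node.k += 1
                    changed = True
            elif isinstance(node, _Branch):
                length = _flat_len(node.children)
                while length - 1 >= 16**node.k:
                    node.k += 1
                    changed = True
                changed = widen(node.children) or changed
        return changed

    def _flat_len(nodes: list) -> int:
        total = 0
        for node in nodes:
            if isinstance(node, _Atom):
                total += 1
            elif isinstance(node, _RingClose):
                total += 1 + node.k
            else:
                total += 1 + node.k + _flat_len(node.children)
        return total

    # index widths and positions depend on each other; iterate to fixpoint
    # (widths only grow, so this terminates quickly)
    layout(root, 0)
    while widen(root):
        layout(root, 0)

    out: list[str] = []

    def emit(nodes: list) -> None:
        for node in nodes:
            if isinstance(node, _Atom):
                out.append(f"[{node.bond}{node.text}]")
            elif isinstance(node, _RingClose):
                value = node.pos - node.opener.pos - 1
                if value < 0:
                    raise SelfiesError("ring closes before it opens")
                out.append(f"[{node.bond}Ring{node.k}]")
                out.extend(_index_digits(value, node.k))
            else:
                out.append(f"[Branch{node.k}]")
                out.extend(_index_digits(_flat_len(node.children) - 1, node.k))
                emit(node.children)

    emit(root)
    return "".join(out)


# --- decoding -------------------------------------------------------------

_SYMBOL = re.compile(r"\[[^\]]*\]")
_RING_RE = re.compile(r"\[([=#\-:]?)Ring(\d)\]")
_BRANCH_RE = re.compile(r"\[Branch(\d)\]")
_ATOM_RE = re.compile(r"\[([=#\-:]?)([^\]]+)\]")

_ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I",
                   "b", "c", "n", "o", "p", "s"}


def split_symbols(selfies: str) -> list[str]:
    """Split a SELFIES string into its bracketed symbols."""
    symbols, pos = [], 0
    for m in _SYMBOL.finditer(selfies):
        if m.start() != pos:
            raise SelfiesError(
                f"malformed SELFIES at position {pos}: {selfies[pos]!r}")
        symbols.append(m.group())
        pos = m.end()
    if pos != len(selfies):
        raise SelfiesError(f"malformed SELFIES at position {pos}")
    if not symbols:
        raise SelfiesError("empty SELFIES string")
    return symbols


class _AtomSlot:
    """One atom in the reconstructed SMILES plus its ring-closure digits."""

    __slots__ = ("text", "digits")

    def __init__(self, text: str):
        self.text = text
        self.digits: list[str] = []

    def render(self) -> str:
        return self.text + "".join(self.digits)


def decode(selfies: str) -> str:
    """Decode back to a SMILES string (up to ring-digit renumbering)."""
    symbols = split_symbols(selfies)
    n = len(symbols)
    pieces: list[object] = []  # _AtomSlot or str
    atom_at_symbol: dict[int, _AtomSlot] = {}
    state = {"ring": 0, "last": None}

    def next_ring_digit() -> str:
        state["ring"] += 1
        num = state["ring"]
        if num > 99:
            raise SelfiesError("too many ring bonds")
        return str(num) if num <= 9 else f"%{num:02d}"

    def read_index(pos: int, k: int) -> tuple[int, int]:
        value = 0
        for j in range(k):
            if pos + j >= n or symbols[pos + j] not in _INDEX_VALUE:
                raise SelfiesError(f"expected index symbol at {pos + j}")
            value = value * 16 + _INDEX_VALUE[symbols[pos + j]]
        return value, pos + k

    def process(pos: int, end: int) -> None:
        while pos < end:
            sym = symbols[pos]
            m = _BRANCH_RE.fullmatch(sym)
            if m:
                k = int(m.group(1))
                q, body = read_index(pos + 1, k)
                stop = body + q + 1
                if stop > end:
                    raise SelfiesError("branch overruns string")
                pieces.append("(")
                process(body, stop)
                pieces.append(")")
                pos = stop
                continue
            m = _RING_RE.fullmatch(sym)
            if m:
                bond, k = m.group(1), int(m.group(2))
                q, nxt = read_index(pos + 1, k)
                opener = atom_at_symbol.get(pos - 1 - q)
                closer = state["last"]
                if opener is None or closer is None:
                    raise SelfiesError(
                        f"ring reference at symbol {pos} does not reach an atom")
                digit = next_ring_digit()
                opener.digits.append(digit)
                closer.digits.append(bond + digit)
                pos = nxt
                continue
            m = _ATOM_RE.fullmatch(sym)
            if m:
                bond, atom = m.groups()
                text = atom if atom in _ORGANIC_SUBSET else f"[{atom}]"
                slot = _AtomSlot(bond + text)
                pieces.append(slot)
                atom_at_symbol[pos] = slot
                state["last"] = slot
                pos += 1
                continue
            raise SelfiesError(f"unrecognized symbol {sym!r}")

    process(0, n)
    return "".join(p.render() if isinstance(p, _AtomSlot) else p for p in pieces)
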