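"""Reading and writing KCF-style atom/bond block records.

The format mirrors the chemical-function block layout used by reaction
databases: an optional ``ENTRY`` line, an ``ATOM`` block declaring the atom
count followed by one line per atom (index, atom type, element, optional
charge), a ``BOND`` block declaring the bond count followed by one line per
bond (serial, endpoint indices, order), and a ``///`` terminator. Bond
orders are written ``1``/``2``/``3`` and ``ar`` for the aromatic order,
which this package keeps distinct from any Kekulé assignment.

Atom-type labels in the input are preserved verbatim; labels outside the
package vocabulary are accepted with a log warning so foreign typing
schemes can round-trip through the parser.
"""

from __future__ import annotations

from .graph import MolecularGraph
from .vocab import check_atom_type

_ORDER_TO_TOKEN = {"single": "1", "double": "2", "triple": "3", "aromatic": "ar"}
_TOKEN_TO_ORDER = {v: k for k, v in _ORDER_TO_TOKEN.items()}


class KCFParseError(ValueError):
    """Malformed KCF-style record; the message names the offending line."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def parse_kcf(text: str) -> MolecularGraph:
    """Parse one KCF-style record into a :class:`MolecularGraph`.

    Raises
    ------
    KCFParseError
        On malformed block headers, count mismatches, duplicate atom
        indices, dangling bond references, or unreadable lines.
    """
    g = MolecularGraph()
    lines = text.splitlines()
    n_atoms = n_bonds = None
    seen_atoms = seen_bonds = 0
    section = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line == "///":
            continue
        fields = line.split()
        head = fields[0]
        if head == "ENTRY":
            g.name = fields[1] if len(fields) > 1 else ""
            section = None
            continue
        if head in ("ATOM", "BOND"):
            try:
                count = int(fields[1])
            except (IndexError, ValueError):
                raise KCFParseError(lineno, f"malformed {head} header {line!r}")
            if count < 0:
                raise KCFParseError(lineno, f"negative {head} count")
            if head == "ATOM":
                n_atoms = count
            else:
                n_bonds = count
            section = head
            continue
        if section == "ATOM":
            if len(fields) < 3:
                raise KCFParseError(lineno, f"malformed atom line {line!r}")
            try:
                idx = int(fields[0])
            except ValueError:
                raise KCFParseError(lineno, f"non-integer atom index {fields[0]!r}")
            atom_type, element = fields[1], fields[2]
            charge = 0
            if len(fields) > 3:
                try:
                    charge = int(fields[3])
                except ValueError:
                    raise KCFParseError(lineno, f"non-integer charge {fields[3]!r}")
            if idx in g:
                raise KCFParseError(lineno, f"duplicate atom index {idx}")
            check_atom_type(atom_type)
            try:
                g.add_atom(element, atom_type, charge, index=idx)
            except ValueError as exc:
                raise KCFParseError(lineno, str(exc))
            seen_atoms += 1
        elif section == "BOND":
            if len(fields) < 4:
                raise KCFParseError(lineno, f"malformed bond line {line!r}")
            try:
                i, j = int(fields[1]), int(fields[2])
            except ValueError:
                raise KCFParseError(lineno, f"non-integer bond endpoint in {line!r}")
            token = fields[3]
            if token not in _TOKEN_TO_ORDER:
                raise KCFParseError(lineno, f"unknown bond order token {token!r}")
            if i not in g or j not in g:
                raise KCFParseError(lineno, f"dangling bond index {i}-{j}")
            try:
                g.add_bond(i, j, _TOKEN_TO_ORDER[token])
            except ValueError as exc:
                raise KCFParseError(lineno, str(exc))
            seen_bonds += 1
        else:
            raise KCFParseError(lineno, f"unexpected line outside blocks: {line!r}")
    if n_atoms is None:
        raise KCFParseError(len(lines) or 1, "missing ATOM block")
    if seen_atoms != n_atoms:
        raise KCFParseError(
            len(lines) or 1, f"ATOM count {n_atoms} != {seen_atoms} atom lines"
        )
    if (n_bonds or 0) != seen_bonds:
        raise KCFParseError(
            len(lines) or 1, f"BOND count {n_bonds or 0} != {seen_bonds} bond lines"
        )
    return g


def write_kcf(g: MolecularGraph) -> str:
    """Serialize *g* to a KCF-style record that re-parses isomorphically."""
    out = []
    if g.name:
        out.append(f"ENTRY       {g.name}")
    out.append(f"ATOM        {g.n_atoms}")
    for atom in g.atoms():
        line = f"            {atom.index:<4d}{atom.atom_type:<8s}{atom.element}"
        if atom.charge:
            line += f" {atom.charge:+d}"
        out.append(line)
    out.append(f"BOND        {g.n_bonds}")
    for serial, bond in enumerate(g.bonds(), start=1):
        i, j = bond.endpoints
        out.append(
            f"            {serial:<4d}{i} {j} {_ORDER_TO_TOKEN[bond.order]}"
        )
    out.append("///")
    return "\n".join(out) + "\n"
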