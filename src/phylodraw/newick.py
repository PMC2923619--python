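"""Newick parsing and canonical serialization.

The grammar accepted is the classic one::

    tree    := subtree ";"
    subtree := leaf | "(" subtree ("," subtree)+ ")" [label] [":" length]
    leaf    := [label] [":" length]

Labels may be quoted with single quotes, ``''`` escaping an embedded quote.
Bracketed comments ``[...]`` outside quotes are stripped (there is no NHX
support).  A purely numeric internal-node label is read as a confidence
(bootstrap) value by default; :class:`NewickDialect` can turn that off, map
unquoted underscores to spaces, or make comments an error.  Exactly one tree
per input is accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional

from .tree import Tree, TreeNode

#: characters that force quoting when serializing a label
_META = set(" \t\n\r()[]':;,")

_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


class NewickParseError(ValueError):
    """Syntax error; carries the character offset where parsing failed."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


@dataclass(frozen=True)
class NewickDialect:
    """Input-dialect switches for ambiguous corners of the Newick format.

    internal_labels_are_confidence:
        Read a purely numeric internal label as a bootstrap/confidence value
        (on by default, matching common practice for inference output).
    unquoted_underscore_to_space:
        Translate ``_`` to space in unquoted labels (PHYLIP convention).
    strip_comments:
        Remove bracketed ``[...]`` comments; when off, a comment is a parse
        error rather than silently kept.
    """

    internal_labels_are_confidence: bool = True
    unquoted_underscore_to_space: bool = False
    strip_comments: bool = True


DEFAULT_DIALECT = NewickDialect()


class _Scanner:
    def __init__(self, text: str, dialect: NewickDialect):
        self.text = text
        self.pos = 0
        self.dialect = dialect

    def error(self, message: str) -> NewickParseError:
        return NewickParseError(message, self.pos)

    def skip_filler(self) -> None:
        """Advance past whitespace and (if enabled) bracketed comments."""
        text = self.text
        while self.pos < len(text):
            ch = text[self.pos]
            if ch.isspace():
                self.pos += 1
            elif ch == "[":
                if not self.dialect.strip_comments:
                    raise self.error("bracketed comment not allowed by dialect")
                end = text.find("]", self.pos + 1)
                if end == -1:
                    raise self.error("unterminated comment")
                self.pos = end + 1
            else:
                return

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def read_quoted_label(self) -> str:
        assert self.text[self.pos] == "'"
        self.pos += 1
        out: List[str] = []
        text = self.text
        while True:
            if self.pos >= len(text):
                raise self.error("unterminated quoted label")
            ch = text[self.pos]
            if ch == "'":
                if self.pos + 1 < len(text) and text[self.pos + 1] == "'":
                    out.append("'")
                    self.pos += 2
                else:
                    self.pos += 1
                    return "".join(out)
            else:
                out.append(ch)
                self.pos += 1

    def read_bare_token(self) -> str:
        """Unquoted label or number: up to the next structural character."""
        start = self.pos
        text = self.text
        while self.pos < len(text) and text[self.pos] not in "()[]':;," and not text[
            self.pos
        ].isspace():
            self.pos += 1
        return text[start:self.pos]


def _parse_length(scanner: _Scanner) -> Optional[float]:
    scanner.skip_filler()
    if scanner.peek() != ":":
        return None
    scanner.pos += 1
    scanner.skip_filler()
    at = scanner.pos
    token = scanner.read_bare_token()
    if not token:
        raise NewickParseError("missing branch length after ':'", at)
    try:
        value = float(token)
    except ValueError:
        raise NewickParseError(f"invalid branch length {token!r}", at) from None
    if value < 0:
        raise NewickParseError(f"negative branch length {token}", at)
    return value


def _parse_subtree(scanner: _Scanner) -> TreeNode:
    scanner.skip_filler()
    node = TreeNode()
    if scanner.peek() == "(":
        open_at = scanner.pos
        scanner.pos += 1
        while True:
            node.children.append(_parse_subtree(scanner))
            scanner.skip_filler()
            ch = scanner.peek()
            if ch == ",":
                scanner.pos += 1
                continue
            if ch == ")":
                scanner.pos += 1
                break
            scanner.pos = open_at
            raise scanner.error("unbalanced parenthesis")
        scanner.skip_filler()
        label = _parse_label(scanner)
        if label is not None:
            quoted, text = label
            if (
                not quoted
                and scanner.dialect.internal_labels_are_confidence
                and _NUMERIC_RE.match(text)
            ):
                node.confidence = float(text)
            else:
                node.label = text
    else:
        label = _parse_label(scanner)
        if label is not None:
            node.label = label[1]
    node.branch_length = _parse_length(scanner)
    return node


def _parse_label(scanner: _Scanner):
    """Return (was_quoted, text) or None if no label is present."""
    scanner.skip_filler()
    ch = scanner.peek()
    if ch == "'":
        return True, scanner.read_quoted_label()
    token = scanner.read_bare_token()
    if not token:
        return None
    if scanner.dialect.unquoted_underscore_to_space:
        token = token.replace("_", " ")
    return False, token


def parse_newick(text: str, dialect: NewickDialect = DEFAULT_DIALECT) -> Tree:
    """Parse a single Newick statement into a :class:`Tree`.

    Raises :class:`NewickParseError` (with character offset) on unbalanced
    parentheses, a missing terminating ``;``, negative branch lengths, empty
    input, or trailing content (multiple trees per file are rejected).
    """
    scanner = _Scanner(text, dialect)
    scanner.skip_filler()
    if scanner.pos >= len(text):
        raise scanner.error("empty input")
    root = _parse_subtree(scanner)
    scanner.skip_filler()
    if scanner.peek() != ";":
        raise scanner.error("expected ';' terminating the tree")
    scanner.pos += 1
    scanner.skip_filler()
    if scanner.pos < len(text):
        raise scanner.error("trailing content after ';' (one tree per file)")
    return Tree.from_root(root)


def _format_number(value: float) -> str:
    """Up to 10 significant digits, trailing zeros trimmed."""
    out = f"{value:.10g}"
    return out


def _format_label(label: str) -> str:
    if label == "" or any(c in _META or c.isspace() for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree) -> str:
    """Canonical Newick: minimal quoting, ``%.10g`` lengths, confidence as
    internal label.  Unit-length (cladogram) trees serialize without ``:``
    segments so the fallback survives a round trip."""

    emit_lengths = not tree.unit_lengths

    def fmt(node: TreeNode, is_root: bool) -> str:
        if node.children:
            inner = ",".join(fmt(c, False) for c in node.children)
            if node.confidence is not None:
                tag = _format_number(node.confidence)
            elif node.label is not None:
                tag = _format_label(node.label)
            else:
                tag = ""
            out = f"({inner}){tag}"
        else:
            out = _format_label(node.label) if node.label is not None else ""
        if emit_lengths and node.branch_length is not None:
            out += ":" + _format_number(node.branch_length)
        return out

    return fmt(tree.root, True) + ";"
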