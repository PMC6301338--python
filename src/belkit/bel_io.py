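"""Parsing, validation and serialization of BEL scripts.

A BEL script expresses biological knowledge as subject–predicate–object
triplets, each qualified by a citation, an evidence sentence and a set of
contextual annotations managed through ``SET``/``UNSET`` blocks.  This
module turns script text into a validated :class:`BelDocument` without
ever raising on malformed input: every line is either consumed into
metadata, definitions or statements, or reported as a :class:`ParseIssue`
with its verbatim line, 1-based line number and 1-based column, so
curators can locate and fix problems quickly.  Recurring issues can be
grouped for triage, and validated documents serialize back to BEL.

Supported surface syntax (a bounded BEL 1.0-style dialect):

* entity functions ``p()``, ``g()``, ``r()``, ``m()``, ``a()``,
  ``complex()``, ``composite()``, ``bp()``, ``path()`` and their long
  forms, over ``NAMESPACE:Name`` terms (names with spaces quoted);
* variants ``pmod(...)`` / ``var(...)`` on gene/RNA/miRNA/protein terms;
* the activity modifier ``act()`` (and ``kin``/``tscript``/``cat``),
  recorded as an edge-side qualifier of the underlying entity node;
* long-form relations plus the short forms ``->``, ``=>``, ``-|``,
  ``=|`` and ``--``;
* ``SET``/``UNSET`` blocks for ``Citation``, ``Evidence`` and annotations;
  ``DEFINE NAMESPACE``/``DEFINE ANNOTATION`` with inline ``LIST`` values,
  local file paths, or unresolved URLs.

Nesting beyond one modifier level is rejected as malformed — the grammar
is deliberately bounded.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .graph_model import RELATIONS, Citation, Node

__all__ = [
    "Namespace",
    "AnnotationDefinition",
    "NodeSpec",
    "Statement",
    "ParseIssue",
    "IssueGroup",
    "BelDocument",
    "parse_bel_document",
    "group_recurring_issues",
    "serialize_bel",
    "load_namespace_file",
]

# ---------------------------------------------------------------------------
# domain types


@dataclass
class Namespace:
    """A controlled vocabulary qualifying entity names.

    ``source`` is ``"inline"`` for LIST definitions, a local file path, or
    ``"unresolved"`` when the definition pointed at a URL that was not
    supplied via the ``resources`` map; ``url`` keeps the original
    location string for round-tripping.
    """

    keyword: str
    source: str = "unresolved"
    terms: frozenset[str] = frozenset()
    url: str = ""

    @property
    def resolved(self) -> bool:
        return self.source != "unresolved"


@dataclass
class AnnotationDefinition:
    keyword: str
    allowed_values: frozenset[str] | str = "unresolved"
    url: str = ""

    @property
    def resolved(self) -> bool:
        return self.allowed_values != "unresolved"


@dataclass(frozen=True, order=True)
class NodeSpec:
    """A node term as written in a statement: entity node + modifier flag."""

    node: Node
    activity: bool = False


@dataclass(frozen=True)
class Statement:
    subject: NodeSpec
    relation: str
    object: NodeSpec
    citation: Optional[Citation]
    evidence: str = ""
    annotations: tuple[tuple[str, tuple[str, ...]], ...] = ()
    line_number: int = 0

    def annotations_dict(self) -> dict[str, set[str]]:
        return {k: set(v) for k, v in self.annotations}

    def key(self) -> tuple:
        """Content identity, ignoring line number."""
        return (self.subject, self.relation, self.object, self.citation,
                self.evidence, self.annotations)


SEVERITIES = ("error", "warning")
CATEGORIES = ("syntactic", "semantic")

#: code -> (severity, category).  Errors reject the statement; warnings keep it.
ISSUE_CODES: dict[str, tuple[str, str]] = {
    "MALFORMED_STATEMENT": ("error", "syntactic"),
    "MALFORMED_SET": ("error", "syntactic"),
    "NAKED_NAME": ("error", "semantic"),
    "UNDEFINED_NAMESPACE": ("error", "semantic"),
    "NAME_NOT_IN_NAMESPACE": ("error", "semantic"),
    "MISSING_CITATION": ("error", "semantic"),
    "UNRESOLVED_NAMESPACE": ("warning", "semantic"),
    "UNDEFINED_ANNOTATION": ("warning", "semantic"),
    "ILLEGAL_ANNOTATION_VALUE": ("warning", "semantic"),
}


@dataclass(frozen=True)
class ParseIssue:
    """One problem found at a specific position of the input."""

    severity: str
    category: str
    code: str
    line_text: str
    line_number: int
    position: int
    token: str = ""

    def __post_init__(self) -> None:
        if self.line_number < 1 or self.position < 1:
            raise ValueError("line_number and position are 1-based")
        if ISSUE_CODES.get(self.code, (self.severity, self.category)) != (
            self.severity,
            self.category,
        ):
            raise ValueError(f"severity/category inconsistent with code {self.code}")

    @property
    def message(self) -> str:
        return f"{self.code} at {self.line_number}:{self.position}: {self.token!r}"


@dataclass(frozen=True)
class IssueGroup:
    code: str
    token: str
    message: str
    count: int
    line_numbers: tuple[int, ...]


@dataclass
class BelDocument:
    metadata: dict[str, str] = field(default_factory=dict)
    namespaces: list[Namespace] = field(default_factory=list)
    annotation_definitions: list[AnnotationDefinition] = field(default_factory=list)
    statements: list[Statement] = field(default_factory=list)
    issues: list[ParseIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ParseIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ParseIssue]:
        return [i for i in self.issues if i.severity == "warning"]


# ---------------------------------------------------------------------------
# lexical helpers

_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")

_FUNCTION_MAP = {
    "p": "protein",
    "proteinAbundance": "protein",
    "g": "gene",
    "geneAbundance": "gene",
    "r": "rna",
    "rnaAbundance": "rna",
    "m": "mirna",
    "microRNAAbundance": "mirna",
    "a": "abundance",
    "abundance": "abundance",
    "complex": "complex",
    "complexAbundance": "complex",
    "composite": "composite",
    "compositeAbundance": "composite",
    "bp": "bioprocess",
    "biologicalProcess": "bioprocess",
    "path": "pathology",
    "pathology": "pathology",
}

_ACTIVITY_FUNCS = {
    "act", "activity", "kin", "kinaseActivity",
    "tscript", "transcriptionalActivity", "cat", "catalyticActivity",
}

_VARIANT_FUNCS = {"pmod", "var"}
_VARIANT_OK_FUNCTIONS = {"gene", "rna", "mirna", "protein"}

_SHORT_RELATIONS = {
    "->": "increases",
    "=>": "directlyIncreases",
    "-|": "decreases",
    "=|": "directlyDecreases",
    "--": "association",
}


class _Reject(Exception):
    """Internal: abort the current line with a single issue."""

    def __init__(self, code: str, position: int, token: str = "") -> None:
        self.code = code
        self.position = position
        self.token = token
        super().__init__(code)


class _Cursor:
    def __init__(self, text: str, start: int = 0) -> None:
        self.text = text
        self.i = start

    @property
    def pos(self) -> int:
        """Current 1-based column."""
        return self.i + 1

    def eof(self) -> bool:
        return self.i >= len(self.text)

    def peek(self) -> str:
        return self.text[self.i] if self.i < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.i < len(self.text) and self.text[self.i] in " \t":
            self.i += 1

    def expect(self, char: str, code: str = "MALFORMED_STATEMENT") -> None:
        if self.peek() != char:
            raise _Reject(code, self.pos, self.peek() or "<end of line>")
        self.i += 1

    def read_ident(self) -> str:
        m = _IDENT_RE.match(self.text, self.i)
        if not m:
            raise _Reject("MALFORMED_STATEMENT", self.pos, self.peek() or "<end of line>")
        self.i = m.end()
        return m.group(0)

    def read_quoted(self) -> str:
        assert self.peek() == '"'
        start = self.pos
        self.i += 1
        out = []
        while self.i < len(self.text):
            c = self.text[self.i]
            if c == "\\" and self.i + 1 < len(self.text):
                out.append(self.text[self.i + 1])
                self.i += 2
                continue
            if c == '"':
                self.i += 1
                return "".join(out)
            out.append(c)
            self.i += 1
        raise _Reject("MALFORMED_STATEMENT", start, "unterminated string")

    def read_balanced(self) -> str:
        """Read a balanced ``(...)`` group, returning the inner text."""
        assert self.peek() == "("
        start = self.pos
        self.i += 1
        depth = 1
        out = []
        while self.i < len(self.text):
            c = self.text[self.i]
            if c == '"':
                out.append('"' + self.read_quoted().replace('"', '\\"') + '"')
                continue
            if c == "(":
                depth += 1
            elif c == ")":
                depth -= 1
                if depth == 0:
                    self.i += 1
                    return "".join(out)
            out.append(c)
            self.i += 1
        raise _Reject("MALFORMED_STATEMENT", start, "unbalanced parentheses")


def _strip_trailing_comment(line: str) -> str:
    """Remove a ``//`` comment that is not inside a quoted string."""
    in_quote = False
    i = 0
    while i < len(line):
        c = line[i]
        if c == "\\" and in_quote:
            i += 2
            continue
        if c == '"':
            in_quote = not in_quote
        elif not in_quote and c == "/" and line[i : i + 2] == "//":
            return line[:i]
        i += 1
    return line


# ---------------------------------------------------------------------------
# term and statement parsing


def _parse_term(cur: _Cursor, depth: int = 0) -> tuple[NodeSpec, int]:
    """Parse one node term; returns (spec, 1-based column of the namespace)."""
    cur.skip_ws()
    start = cur.pos
    ident = cur.read_ident()
    if cur.peek() != "(":
        # a bare token where a function term is required
        raise _Reject("MALFORMED_STATEMENT", start, ident)
    if ident in _ACTIVITY_FUNCS:
        if depth >= 1:
            raise _Reject("MALFORMED_STATEMENT", start, ident)
        cur.expect("(")
        inner, ns_pos = _parse_term(cur, depth + 1)
        cur.skip_ws()
        cur.expect(")")
        return NodeSpec(inner.node, activity=True), ns_pos
    if ident not in _FUNCTION_MAP:
        raise _Reject("MALFORMED_STATEMENT", start, ident)
    function = _FUNCTION_MAP[ident]
    cur.expect("(")
    cur.skip_ws()
    ns_pos = cur.pos
    if cur.peek() == '"':
        name = cur.read_quoted()
        raise _Reject("NAKED_NAME", ns_pos, name)
    namespace = cur.read_ident()
    cur.skip_ws()
    if cur.peek() != ":":
        raise _Reject("NAKED_NAME", ns_pos, namespace)
    cur.i += 1
    cur.skip_ws()
    if cur.peek() == '"':
        name = cur.read_quoted()
    else:
        name = cur.read_ident()
    variants: list[str] = []
    cur.skip_ws()
    while cur.peek() == ",":
        cur.i += 1
        cur.skip_ws()
        vstart = cur.pos
        vfunc = cur.read_ident()
        if vfunc not in _VARIANT_FUNCS or cur.peek() != "(":
            raise _Reject("MALFORMED_STATEMENT", vstart, vfunc)
        if function not in _VARIANT_OK_FUNCTIONS:
            raise _Reject("MALFORMED_STATEMENT", vstart, vfunc)
        inner = cur.read_balanced().strip()
        variants.append(f"{vfunc}({inner})")
        cur.skip_ws()
    cur.expect(")")
    return NodeSpec(Node(function, namespace, name, tuple(variants))), ns_pos


def _parse_relation(cur: _Cursor) -> str:
    cur.skip_ws()
    start = cur.pos
    two = cur.text[cur.i : cur.i + 2]
    if two in _SHORT_RELATIONS:
        cur.i += 2
        return _SHORT_RELATIONS[two]
    m = _IDENT_RE.match(cur.text, cur.i)
    if not m:
        raise _Reject("MALFORMED_STATEMENT", start, cur.peek() or "<end of line>")
    word = m.group(0)
    if word not in RELATIONS:
        raise _Reject("MALFORMED_STATEMENT", start, word)
    cur.i = m.end()
    return word


# ---------------------------------------------------------------------------
# control lines

_SET_DOC_RE = re.compile(r'^\s*SET\s+DOCUMENT\s+(\w+)\s*=\s*"')
_SET_RE = re.compile(r"^\s*SET\s+(\w+)\s*=\s*")
_UNSET_RE = re.compile(r"^\s*UNSET\s+(\w+|ALL)\s*$")
_DEFINE_RE = re.compile(
    r"^\s*DEFINE\s+(NAMESPACE|ANNOTATION)\s+(\w+)\s+AS\s+(URL|LIST)\s*", re.IGNORECASE
)


def _read_string_list(cur: _Cursor) -> list[str]:
    """Parse ``{"a", "b", ...}``."""
    cur.skip_ws()
    cur.expect("{", "MALFORMED_SET")
    values = []
    while True:
        cur.skip_ws()
        if cur.peek() == "}":
            cur.i += 1
            break
        if cur.peek() != '"':
            raise _Reject("MALFORMED_SET", cur.pos, cur.peek() or "<end of line>")
        values.append(cur.read_quoted())
        cur.skip_ws()
        if cur.peek() == ",":
            cur.i += 1
        elif cur.peek() == "}":
            cur.i += 1
            break
        else:
            raise _Reject("MALFORMED_SET", cur.pos, cur.peek() or "<end of line>")
    return values


def _citation_from_fields(fields: Sequence[str], position: int) -> Citation:
    """Build a citation from the 2-, 3- or up to 6-field SET Citation form."""
    if len(fields) == 2:
        db_type, name, reference = fields[0], "", fields[1]
        date, authors = None, ()
    elif 3 <= len(fields) <= 6:
        db_type, name, reference = fields[0], fields[1], fields[2]
        date = fields[3] if len(fields) > 3 and fields[3] else None
        authors = tuple(a for a in fields[4].split("|") if a) if len(fields) > 4 else ()
    else:
        raise _Reject("MALFORMED_SET", position, "Citation")
    if not db_type or not reference:
        raise _Reject("MALFORMED_SET", position, "Citation")
    return Citation(db_type, reference, name, authors, date)


def load_namespace_file(path: str) -> frozenset[str]:
    """Load a namespace term list: one name per line, ``#`` comments ignored."""
    terms = set()
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if line and not line.startswith("#"):
                terms.add(line)
    return frozenset(terms)


# ---------------------------------------------------------------------------
# the parser


class _ParserState:
    def __init__(self) -> None:
        self.citation: Optional[Citation] = None
        self.evidence: str = ""
        self.annotations: dict[str, frozenset[str]] = {}

    def unset(self, key: str) -> None:
        if key == "ALL":
            self.__init__()
        elif key in ("Citation",):
            self.citation = None
        elif key in ("Evidence", "SupportingText"):
            self.evidence = ""
        else:
            self.annotations.pop(key, None)


def parse_bel_document(
    text: str,
    resources: Optional[Mapping[str, Namespace]] = None,
) -> BelDocument:
    """Parse BEL script text into a validated :class:`BelDocument`.

    Never raises on malformed input: each input line either contributes to
    the document or produces at least one :class:`ParseIssue`.  Statements
    inherit the currently SET citation, evidence and annotations; ``UNSET``
    removes keys.  ``resources`` maps namespace keywords to pre-resolved
    :class:`Namespace` objects, overriding URL definitions.
    """
    resources = dict(resources or {})
    doc = BelDocument()
    namespaces: dict[str, Namespace] = {}
    annot_defs: dict[str, AnnotationDefinition] = {}
    state = _ParserState()

    def issue(code: str, raw: str, lineno: int, position: int, token: str = "") -> None:
        severity, category = ISSUE_CODES[code]
        doc.issues.append(
            ParseIssue(severity, category, code, raw, lineno, max(position, 1), token)
        )

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = _strip_trailing_comment(raw)
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue

        try:
            if _DEFINE_RE.match(line):
                _handle_define(line, namespaces, annot_defs, resources)
                continue
            m = _SET_DOC_RE.match(line)
            if m:
                cur = _Cursor(line, m.end() - 1)
                doc.metadata[m.group(1)] = cur.read_quoted()
                continue
            m = _SET_RE.match(line)
            if m:
                _handle_set(line, m, state, annot_defs, issue, raw, lineno)
                continue
            m = _UNSET_RE.match(line)
            if m:
                state.unset(m.group(1))
                continue
            if stripped.startswith(("SET ", "SET\t", "UNSET", "DEFINE ")):
                raise _Reject("MALFORMED_SET", 1, stripped.split()[0])

            # otherwise: a statement line
            cur = _Cursor(line)
            subject, subj_ns_pos = _parse_term(cur)
            relation = _parse_relation(cur)
            obj, obj_ns_pos = _parse_term(cur)
            cur.skip_ws()
            if not cur.eof():
                raise _Reject("MALFORMED_STATEMENT", cur.pos, cur.text[cur.i :].strip())

            # semantic validation: citation, then namespaces
            if state.citation is None:
                raise _Reject("MISSING_CITATION", 1, relation)
            for spec, ns_pos in ((subject, subj_ns_pos), (obj, obj_ns_pos)):
                ns_kw = spec.node.namespace
                ns = namespaces.get(ns_kw)
                if ns is None:
                    raise _Reject("UNDEFINED_NAMESPACE", ns_pos, ns_kw)
                if ns.resolved and spec.node.name not in ns.terms:
                    raise _Reject("NAME_NOT_IN_NAMESPACE", ns_pos, spec.node.name)
                if not ns.resolved:
                    issue("UNRESOLVED_NAMESPACE", raw, lineno, ns_pos, ns_kw)

            doc.statements.append(
                Statement(
                    subject=subject,
                    relation=relation,
                    object=obj,
                    citation=state.citation,
                    evidence=state.evidence,
                    annotations=tuple(
                        sorted((k, tuple(sorted(v))) for k, v in state.annotations.items())
                    ),
                    line_number=lineno,
                )
            )
        except _Reject as rej:
            issue(rej.code, raw, lineno, rej.position, rej.token)

    doc.namespaces = list(namespaces.values())
    doc.annotation_definitions = list(annot_defs.values())
    return doc


def _handle_define(
    line: str,
    namespaces: dict[str, Namespace],
    annot_defs: dict[str, AnnotationDefinition],
    resources: Mapping[str, Namespace],
) -> None:
    m = _DEFINE_RE.match(line)
    assert m is not None
    kind, keyword, how = m.group(1).upper(), m.group(2), m.group(3).upper()
    cur = _Cursor(line, m.end())
    if how == "LIST":
        values = frozenset(_read_string_list(cur))
        if kind == "NAMESPACE":
            namespaces[keyword] = Namespace(keyword, "inline", values)
        else:
            annot_defs[keyword] = AnnotationDefinition(keyword, values)
        return
    cur.skip_ws()
    if cur.peek() != '"':
        raise _Reject("MALFORMED_SET", cur.pos, cur.peek() or "<end of line>")
    url = cur.read_quoted()
    if kind == "NAMESPACE":
        if keyword in resources:
            ns = resources[keyword]
            namespaces[keyword] = Namespace(keyword, ns.source or "resource", ns.terms, url)
        elif os.path.isfile(url):
            namespaces[keyword] = Namespace(keyword, url, load_namespace_file(url), url)
        else:
            namespaces[keyword] = Namespace(keyword, "unresolved", frozenset(), url)
    else:
        if os.path.isfile(url):
            annot_defs[keyword] = AnnotationDefinition(keyword, load_namespace_file(url), url)
        else:
            annot_defs[keyword] = AnnotationDefinition(keyword, "unresolved", url)


def _handle_set(
    line: str,
    m: re.Match,
    state: _ParserState,
    annot_defs: Mapping[str, AnnotationDefinition],
    issue,
    raw: str,
    lineno: int,
) -> None:
    key = m.group(1)
    cur = _Cursor(line, m.end())
    cur.skip_ws()
    if key == "Citation":
        fields = _read_string_list(cur)
        state.citation = _citation_from_fields(fields, m.start(1) + 1)
        return
    if key in ("Evidence", "SupportingText"):
        if cur.peek() != '"':
            raise _Reject("MALFORMED_SET", cur.pos, cur.peek() or "<end of line>")
        state.evidence = cur.read_quoted()
        return
    # an annotation
    if cur.peek() == "{":
        values = frozenset(_read_string_list(cur))
    elif cur.peek() == '"':
        values = frozenset({cur.read_quoted()})
    else:
        raise _Reject("MALFORMED_SET", cur.pos, cur.peek() or "<end of line>")
    definition = annot_defs.get(key)
    if definition is None:
        issue("UNDEFINED_ANNOTATION", raw, lineno, m.start(1) + 1, key)
    elif definition.resolved:
        for value in sorted(values - set(definition.allowed_values)):
            issue("ILLEGAL_ANNOTATION_VALUE", raw, lineno, m.start(1) + 1, value)
    state.annotations[key] = values


# ---------------------------------------------------------------------------
# issue grouping


def group_recurring_issues(issues: Iterable[ParseIssue]) -> list[IssueGroup]:
    """Group issues by (code, offending token), most frequent first.

    Ties are broken by the first line number, ascending.  The counts of
    the returned groups always sum to the number of input issues.
    """
    buckets: dict[tuple[str, str], list[ParseIssue]] = {}
    for iss in issues:
        buckets.setdefault((iss.code, iss.token), []).append(iss)
    groups = [
        IssueGroup(
            code=code,
            token=token,
            message=f"{code}: {token!r} ({len(members)}x)",
            count=len(members),
            line_numbers=tuple(sorted(i.line_number for i in members)),
        )
        for (code, token), members in buckets.items()
    ]
    groups.sort(key=lambda g: (-g.count, g.line_numbers[0]))
    return groups


# ---------------------------------------------------------------------------
# serialization


def _bel_string(value: str) -> str:
    return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _spec_to_bel(spec: NodeSpec) -> str:
    term = spec.node.as_bel()
    return f"act({term})" if spec.activity else term


def serialize_bel(document: BelDocument) -> str:
    """Serialize a validated document back to BEL script text.

    Annotation SET lines are emitted in lexicographic key order and term
    lists in sorted order, so serialization is canonical: re-parsing
    yields the same statement multiset.

    Raises ``ValueError`` if the document carries error-severity issues.
    """
    if document.errors:
        raise ValueError(
            f"cannot serialize a document with {len(document.errors)} error(s)"
        )
    lines: list[str] = []
    for key in sorted(document.metadata):
        lines.append(f"SET DOCUMENT {key} = {_bel_string(document.metadata[key])}")
    for ns in sorted(document.namespaces, key=lambda n: n.keyword):
        if ns.source == "inline":
            terms = ", ".join(_bel_string(t) for t in sorted(ns.terms))
            lines.append(f"DEFINE NAMESPACE {ns.keyword} AS LIST {{{terms}}}")
        else:
            lines.append(
                f"DEFINE NAMESPACE {ns.keyword} AS URL "
                f"{_bel_string(ns.url or ns.source)}"
            )
    for ad in sorted(document.annotation_definitions, key=lambda a: a.keyword):
        if ad.resolved:
            values = ", ".join(_bel_string(v) for v in sorted(ad.allowed_values))
            lines.append(f"DEFINE ANNOTATION {ad.keyword} AS LIST {{{values}}}")
        else:
            lines.append(
                f"DEFINE ANNOTATION {ad.keyword} AS URL {_bel_string(ad.url or 'unresolved')}"
            )
    for statement in document.statements:
        lines.append("")
        cit = statement.citation
        if cit is not None:
            fields = [cit.db_type, cit.name, cit.reference, cit.date or "",
                      "|".join(cit.authors), ""]
            while len(fields) > 3 and fields[-1] == "":
                fields.pop()
            joined = ", ".join(_bel_string(f) for f in fields)
            lines.append(f"SET Citation = {{{joined}}}")
        if statement.evidence:
            lines.append(f"SET Evidence = {_bel_string(statement.evidence)}")
        for key, values in statement.annotations:
            joined = ", ".join(_bel_string(v) for v in values)
            lines.append(f"SET {key} = {{{joined}}}")
        lines.append(
            f"{_spec_to_bel(statement.subject)} {statement.relation} "
            f"{_spec_to_bel(statement.object)}"
        )
        lines.append("UNSET ALL")
    return "\n".join(lines) + "\n"
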