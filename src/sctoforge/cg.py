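"""SNOMED CT compositional-grammar expressions: AST, parser, serializer.

Two dialects are supported.  ``standard`` follows the usual compositional
grammar style: ``===``/``<<<`` definition status, ``+`` or ``,`` between
focus concepts, ``attr = value`` refinements after a ``:``, attribute groups
in braces, nested expressions in parentheses after ``=``.  ``paper`` is a
looser dialect found in older worked examples: the definition-status symbol
may appear infix after a defined subject, ``attr value`` juxtaposition is
read as ``attr = value``, a parenthesized attribute set standing where an
attribute or focus concept is expected is an attribute group, and the ``:``
before a refinement is optional.

Terms (the ``|...|`` labels) carry no semantics: two references with the
same SCTID compare equal regardless of label, so stripping terms never
changes parsed meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Literal, Union

Status = Literal["equivalent", "subtype"]

STATUS_SYMBOL = {"equivalent": "===", "subtype": "<<<"}


class CGParseError(ValueError):
    """Malformed compositional-grammar text; carries the character offset."""

    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class ConceptRef:
    """A concept reference ``sctid |term|``; the term is display-only."""

    sctid: str
    term: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.sctid or not self.sctid.isdigit():
            raise ValueError(f"SCTID must be a non-empty digit string, got {self.sctid!r}")


@dataclass(frozen=True)
class ConcreteValue:
    """A primitive attribute value: ``#500`` (numeric) or ``"text"``."""

    kind: Literal["numeric", "string"]
    numeric_value: Decimal | None = None
    text_value: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "numeric" and self.numeric_value is None:
            raise ValueError("numeric ConcreteValue needs numeric_value")
        if self.kind == "string" and self.text_value is None:
            raise ValueError("string ConcreteValue needs text_value")


AttributeValue = Union[ConceptRef, "CGExpression", ConcreteValue]


@dataclass(frozen=True)
class CGAttribute:
    name: ConceptRef
    value: AttributeValue


@dataclass(frozen=True)
class CGExpression:
    """One compositional-grammar expression.

    ``subject`` holds an optional defined left-hand side (a concept reference
    or a free-text label) when the text uses the infix definition form
    ``<subject> === <expression>``; it is bookkeeping only and takes no part
    in translation to description logic.
    """

    status: Status = "equivalent"
    focus: tuple[ConceptRef, ...] = ()
    ungrouped: tuple[CGAttribute, ...] = ()
    groups: tuple[tuple[CGAttribute, ...], ...] = ()
    subject: ConceptRef | str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.focus:
            raise ValueError("expression must have at least one focus concept")
        for g in self.groups:
            if not g:
                raise ValueError("attribute groups must be non-empty")

    def attributes(self) -> tuple[CGAttribute, ...]:
        """All attributes, ungrouped first, then group by group."""
        out = list(self.ungrouped)
        for g in self.groups:
            out.extend(g)
        return tuple(out)

    def find_attribute(self, name_sctid: str) -> CGAttribute | None:
        """First attribute (ungrouped or grouped) with the given name SCTID."""
        for a in self.attributes():
            if a.name.sctid == name_sctid:
                return a
        return None


# ---------------------------------------------------------------------------
# Tokenizer


@dataclass(frozen=True)
class _Token:
    kind: str  # SCTID WORD TERM NUMBER STRING SYMBOL EOF
    value: str
    offset: int


_SYMBOLS = ("===", "<<<", ":", ",", "=", "{", "}", "(", ")", "+", "#")


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if text.startswith("===", i):
            tokens.append(_Token("SYMBOL", "===", i)); i += 3
            continue
        if text.startswith("<<<", i):
            tokens.append(_Token("SYMBOL", "<<<", i)); i += 3
            continue
        if ch == "|":
            end = text.find("|", i + 1)
            if end < 0:
                raise CGParseError("unterminated |term|", i)
            tokens.append(_Token("TERM", text[i + 1:end], i))
            i = end + 1
            continue
        if ch == '"':
            end = text.find('"', i + 1)
            if end < 0:
                raise CGParseError("unterminated string literal", i)
            tokens.append(_Token("STRING", text[i + 1:end], i))
            i = end + 1
            continue
        if ch == "#":
            j = i + 1
            while j < n and (text[j].isdigit() or text[j] in ".-"):
                j += 1
            if j == i + 1:
                raise CGParseError("'#' must be followed by a number", i)
            tokens.append(_Token("NUMBER", text[i + 1:j], i))
            i = j
            continue
        if ch.isdigit():
            j = i
            while j < n and text[j].isdigit():
                j += 1
            tokens.append(_Token("SCTID", text[i:j], i))
            i = j
            continue
        if ch in ":,={}()+":
            tokens.append(_Token("SYMBOL", ch, i)); i += 1
            continue
        if ch.isalpha():
            j = i
            while j < n and (text[j].isalnum() or text[j] in "'-_/"):
                j += 1
            tokens.append(_Token("WORD", text[i:j], i))
            i = j
            continue
        raise CGParseError(f"unexpected character {ch!r}", i)
    tokens.append(_Token("EOF", "", n))
    return tokens


# ---------------------------------------------------------------------------
# Parser

Dialect = Literal["paper", "standard"]


class _Parser:
    def __init__(self, tokens: list[_Token], dialect: Dialect) -> None:
        self.toks = tokens
        self.pos = 0
        self.dialect = dialect

    @property
    def cur(self) -> _Token:
        return self.toks[self.pos]

    def advance(self) -> _Token:
        tok = self.toks[self.pos]
        self.pos += 1
        return tok

    def at_symbol(self, *symbols: str) -> bool:
        return self.cur.kind == "SYMBOL" and self.cur.value in symbols

    def expect_symbol(self, symbol: str) -> None:
        if not self.at_symbol(symbol):
            raise CGParseError(f"expected {symbol!r}, found {self.cur.value or self.cur.kind!r}",
                               self.cur.offset)
        self.advance()

    # -- grammar -----------------------------------------------------------

    def parse_concept_ref(self) -> ConceptRef:
        if self.cur.kind != "SCTID":
            raise CGParseError(f"expected SCTID, found {self.cur.value or self.cur.kind!r}",
                               self.cur.offset)
        sctid = self.advance().value
        term = None
        if self.cur.kind == "TERM":
            term = self.advance().value
        return ConceptRef(sctid, term)

    def parse_attribute_value(self) -> AttributeValue:
        if self.cur.kind == "NUMBER":
            tok = self.advance()
            return ConcreteValue("numeric", numeric_value=Decimal(tok.value))
        if self.cur.kind == "STRING":
            return ConcreteValue("string", text_value=self.advance().value)
        if self.at_symbol("("):
            self.advance()
            expr = self.parse_expression_body()
            self.expect_symbol(")")
            return expr
        return self.parse_concept_ref()

    def parse_attribute(self) -> CGAttribute:
        name = self.parse_concept_ref()
        if self.at_symbol("="):
            self.advance()
            return CGAttribute(name, self.parse_attribute_value())
        if self.dialect == "paper" and self.cur.kind in ("SCTID", "NUMBER", "STRING"):
            # juxtaposition: "363698007 |finding site| 113331007" reads as name = value
            return CGAttribute(name, self.parse_attribute_value())
        raise CGParseError("expected '=' in attribute", self.cur.offset)

    def parse_attribute_set(self, closer: str) -> tuple[CGAttribute, ...]:
        attrs = [self.parse_attribute()]
        while self.at_symbol(","):
            self.advance()
            attrs.append(self.parse_attribute())
        if not self.at_symbol(closer):
            raise CGParseError(f"expected {closer!r} to close attribute group", self.cur.offset)
        self.advance()
        return tuple(attrs)

    def _item_is_attribute(self) -> bool:
        """Lookahead: does an SCTID at the current position start an attribute?"""
        nxt = self.pos + 1
        if self.toks[nxt].kind == "TERM":
            nxt += 1
        follow = self.toks[nxt]
        if follow.kind == "SYMBOL" and follow.value == "=":
            return True
        if self.dialect == "paper" and follow.kind in ("SCTID", "NUMBER", "STRING"):
            return True
        return False

    def parse_expression_body(self, status: Status = "equivalent",
                              subject: ConceptRef | str | None = None) -> CGExpression:
        if self.at_symbol("===", "<<<"):
            status = "equivalent" if self.advance().value == "===" else "subtype"
        focus: list[ConceptRef] = []
        ungrouped: list[CGAttribute] = []
        groups: list[tuple[CGAttribute, ...]] = []
        in_refinement = False

        while True:
            if self.at_symbol("{"):
                self.advance()
                groups.append(self.parse_attribute_set("}"))
                in_refinement = True
            elif self.at_symbol("(") and self.dialect == "paper" and (in_refinement or focus):
                # parenthesized attribute set at item position = attribute group
                self.advance()
                groups.append(self.parse_attribute_set(")"))
                in_refinement = True
            elif self.cur.kind == "SCTID":
                if in_refinement or self._item_is_attribute():
                    ungrouped.append(self.parse_attribute())
                    in_refinement = in_refinement or True
                else:
                    focus.append(self.parse_concept_ref())
            else:
                raise CGParseError(
                    f"expected concept reference, attribute, or group, found "
                    f"{self.cur.value or self.cur.kind!r}", self.cur.offset)

            if self.at_symbol(","):
                self.advance()
                continue
            if self.at_symbol("+") and not in_refinement:
                if self.dialect != "standard":
                    raise CGParseError("'+' between focus concepts needs dialect=standard",
                                       self.cur.offset)
                self.advance()
                continue
            if self.at_symbol(":"):
                if in_refinement:
                    raise CGParseError("unexpected second ':'", self.cur.offset)
                self.advance()
                in_refinement = True
                continue
            break

        if not focus:
            raise CGParseError("expression has no focus concept", self.cur.offset)
        return CGExpression(status=status, focus=tuple(focus),
                            ungrouped=tuple(ungrouped), groups=tuple(groups),
                            subject=subject)


def _split_subject(text: str) -> tuple[str | None, Status, str]:
    """Split ``<subject> === <body>`` at the first status symbol that sits
    outside parentheses, braces, and ``|...|`` terms."""
    depth = 0
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "|":
            end = text.find("|", i + 1)
            i = len(text) if end < 0 else end + 1
            continue
        if ch in "({":
            depth += 1
        elif ch in ")}":
            depth -= 1
        elif depth == 0 and text.startswith(("===", "<<<"), i):
            status: Status = "equivalent" if text.startswith("===", i) else "subtype"
            return text[:i].strip() or None, status, text[i + 3:]
        i += 1
    return None, "equivalent", text


def parse_cg(text: str, dialect: Dialect = "paper") -> CGExpression:
    """Parse one compositional-grammar expression into its AST."""
    if not text or not text.strip():
        raise CGParseError("empty expression", 0)
    subject_text, status, body = _split_subject(text)

    subject: ConceptRef | str | None = None
    if subject_text is not None:
        try:
            toks = _tokenize(subject_text)
            if (len(toks) in (2, 3) and toks[0].kind == "SCTID"
                    and all(t.kind in ("SCTID", "TERM", "EOF") for t in toks)):
                term = next((t.value for t in toks if t.kind == "TERM"), None)
                subject = ConceptRef(toks[0].value, term)
            else:
                subject = subject_text
        except CGParseError:
            subject = subject_text

    offset_base = len(text) - len(body)
    try:
        tokens = _tokenize(body)
        parser = _Parser(tokens, dialect)
        expr = parser.parse_expression_body(status=status, subject=subject)
        if parser.cur.kind != "EOF":
            raise CGParseError(f"trailing input {parser.cur.value!r}", parser.cur.offset)
    except CGParseError as exc:
        raise CGParseError(str(exc).rsplit(" (at offset", 1)[0],
                           exc.offset + offset_base) from None
    except ValueError as exc:
        raise CGParseError(str(exc), offset_base) from None
    return expr


def strip_terms(text: str) -> str:
    """Remove all ``|...|`` labels from expression text."""
    out: list[str] = []
    i = 0
    while i < len(text):
        if text[i] == "|":
            end = text.find("|", i + 1)
            if end < 0:
                out.append(text[i:])
                break
            i = end + 1
        else:
            out.append(text[i])
            i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# Serializer


def _serialize_ref(ref: ConceptRef, with_terms: bool) -> str:
    if with_terms and ref.term is not None:
        return f"{ref.sctid} |{ref.term}|"
    return ref.sctid


def _serialize_value(value: AttributeValue, with_terms: bool) -> str:
    if isinstance(value, ConceptRef):
        return _serialize_ref(value, with_terms)
    if isinstance(value, ConcreteValue):
        if value.kind == "numeric":
            return f"#{value.numeric_value}"
        return f'"{value.text_value}"'
    return f"({serialize_cg(value, with_terms)})"


def _serialize_attr(attr: CGAttribute, with_terms: bool) -> str:
    return f"{_serialize_ref(attr.name, with_terms)} = {_serialize_value(attr.value, with_terms)}"


def serialize_cg(expr: CGExpression, with_terms: bool = False) -> str:
    """Canonical text: focus concepts comma-joined, ``:`` before refinement,
    groups in braces.  The status symbol appears only for subtype expressions
    (``===`` is the default) unless a subject is present, in which case the
    infix definition form is reproduced."""
    parts: list[str] = []
    if expr.subject is not None:
        if isinstance(expr.subject, ConceptRef):
            parts.append(_serialize_ref(expr.subject, with_terms))
        elif with_terms:
            parts.append(expr.subject)
        if parts:
            parts.append(STATUS_SYMBOL[expr.status])
        elif expr.status == "subtype":
            parts.append("<<<")
    elif expr.status == "subtype":
        parts.append("<<<")

    head = ", ".join(_serialize_ref(f, with_terms) for f in expr.focus)
    items = [_serialize_attr(a, with_terms) for a in expr.ungrouped]
    items += ["{" + ", ".join(_serialize_attr(a, with_terms) for a in g) + "}"
              for g in expr.groups]
    text = head + (": " + ", ".join(items) if items else "")
    parts.append(text)
    return " ".join(parts)
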