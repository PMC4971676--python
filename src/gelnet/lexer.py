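"""Tokenizer for the Gel dialect (scripts, graph literals, expressions).

One lexical subtlety is worth spelling out: the dotted operators ``.+ .- .&``
begin with a dot, and so do real literals like ``.5``.  A dot followed by a
digit starts a real literal only when the previous significant token could
not end a value (identifier, literal, or a closing bracket); otherwise the
dotted-operator reading wins.  Inside a number, a dot is consumed only when
a digit follows, so ``1.+2`` lexes as ``1`` ``.+`` ``2`` while ``0.4`` is a
single real literal.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Token", "TokenStream", "tokenize", "quote_string", "GelSyntaxError"]


class GelSyntaxError(SyntaxError):
    def __init__(self, message: str, line: int, col: int):
        super().__init__(f"{message} (line {line}, column {col})")
        self.line = line
        self.col = col


@dataclass(frozen=True)
class Token:
    kind: str  # IDENT | INT | REAL | STRING | OP | EOF
    value: object
    line: int
    col: int

    def __repr__(self):  # compact, for error messages
        return f"{self.kind}({self.value!r})"


# longest first so maximal munch is a linear scan
_OPERATORS = [
    ".+=", ".-=", ".&=", "**=",
    ".+", ".-", ".&", "**", "->", "<=", ">=", "==", "!=", ":=",
    "+=", "-=", "*=", "&=",
    "+", "-", "*", "/", "&", "<", ">", "=",
    "(", ")", "[", "]", "{", "}", ",", ";", ":",
]

_ESCAPES = {"n": "\n", "t": "\t", "r": "\r", '"': '"', "\\": "\\"}
_REV_ESCAPES = {"\n": "\\n", "\t": "\\t", "\r": "\\r", '"': '\\"', "\\": "\\\\"}


def quote_string(s: str) -> str:
    """Render *s* as a double-quoted Gel string literal."""
    return '"' + "".join(_REV_ESCAPES.get(c, c) for c in s) + '"'

# tokens after which a dot must be an operator, never the start of a real
_VALUE_ENDERS = {"IDENT", "INT", "REAL", "STRING"}
_CLOSERS = {")", "]", "}"}


def _is_ident_start(c: str) -> bool:
    return c.isalpha() or c == "_"


def _is_ident(c: str) -> bool:
    return c.isalnum() or c == "_"


def tokenize(text: str) -> list[Token]:
    tokens: list[Token] = []
    i, line, col = 0, 1, 1
    n = len(text)

    def prev_ends_value() -> bool:
        if not tokens:
            return False
        t = tokens[-1]
        return t.kind in _VALUE_ENDERS or (t.kind == "OP" and t.value in _CLOSERS)

    while i < n:
        c = text[i]
        if c == "\n":
            i += 1
            line += 1
            col = 1
            continue
        if c in " \t\r":
            i += 1
            col += 1
            continue
        if c == "#":  # comment to end of line
            while i < n and text[i] != "\n":
                i += 1
            continue
        start_line, start_col = line, col

        if c == '"':
            i += 1
            col += 1
            buf = []
            while True:
                if i >= n or text[i] == "\n":
                    raise GelSyntaxError("unterminated string", start_line, start_col)
                ch = text[i]
                if ch == '"':
                    i += 1
                    col += 1
                    break
                if ch == "\\":
                    if i + 1 >= n:
                        raise GelSyntaxError("bad escape", line, col)
                    esc = text[i + 1]
                    if esc == "u":
                        hexpart = text[i + 2 : i + 6]
                        if len(hexpart) < 4:
                            raise GelSyntaxError("bad \\u escape", line, col)
                        buf.append(chr(int(hexpart, 16)))
                        i += 6
                        col += 6
                        continue
                    if esc not in _ESCAPES:
                        raise GelSyntaxError(f"bad escape \\{esc}", line, col)
                    buf.append(_ESCAPES[esc])
                    i += 2
                    col += 2
                    continue
                buf.append(ch)
                i += 1
                col += 1
            tokens.append(Token("STRING", "".join(buf), start_line, start_col))
            continue

        is_num = c.isdigit() or (c == "." and i + 1 < n and text[i + 1].isdigit()
                                 and not prev_ends_value())
        if is_num:
            j = i
            seen_dot = seen_exp = False
            while j < n:
                ch = text[j]
                if ch.isdigit():
                    j += 1
                elif ch == "." and not seen_dot and not seen_exp \
                        and j + 1 < n and text[j + 1].isdigit():
                    seen_dot = True
                    j += 1
                elif ch in "eE" and not seen_exp and j + 1 < n \
                        and (text[j + 1].isdigit()
                             or (text[j + 1] in "+-" and j + 2 < n and text[j + 2].isdigit())):
                    seen_exp = True
                    j += 2 if text[j + 1] in "+-" else 1
                else:
                    break
            lit = text[i:j]
            if seen_dot or seen_exp or (c == "."):
                tokens.append(Token("REAL", float(lit), start_line, start_col))
            else:
                tokens.append(Token("INT", int(lit), start_line, start_col))
            col += j - i
            i = j
            continue

        if _is_ident_start(c):
            j = i
            while j < n and _is_ident(text[j]):
                j += 1
            tokens.append(Token("IDENT", text[i:j], start_line, start_col))
            col += j - i
            i = j
            continue

        for op in _OPERATORS:
            if text.startswith(op, i):
                tokens.append(Token("OP", op, start_line, start_col))
                i += len(op)
                col += len(op)
                break
        else:
            raise GelSyntaxError(f"illegal character {c!r}", line, col)

    tokens.append(Token("EOF", None, line, col))
    return tokens


class TokenStream:
    """Cursor over a token list with peek/expect helpers."""

    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.pos = 0

    def peek(self, ahead: int = 0) -> Token:
        return self.tokens[min(self.pos + ahead, len(self.tokens) - 1)]

    def next(self) -> Token:
        t = self.peek()
        if t.kind != "EOF":
            self.pos += 1
        return t

    def at_op(self, *ops: str) -> bool:
        t = self.peek()
        return t.kind == "OP" and t.value in ops

    def at_ident(self, *names: str) -> bool:
        t = self.peek()
        return t.kind == "IDENT" and (not names or t.value in names)

    def accept_op(self, *ops: str) -> Token | None:
        if self.at_op(*ops):
            return self.next()
        return None

    def expect_op(self, op: str) -> Token:
        t = self.peek()
        if not self.at_op(op):
            raise GelSyntaxError(f"expected {op!r}, found {t}", t.line, t.col)
        return self.next()

    def expect_ident(self, *names: str) -> Token:
        t = self.peek()
        if t.kind != "IDENT" or (names and t.value not in names):
            what = " or ".join(repr(x) for x in names) if names else "identifier"
            raise GelSyntaxError(f"expected {what}, found {t}", t.line, t.col)
        return self.next()

    def expect_eof(self) -> None:
        t = self.peek()
        if t.kind != "EOF":
            raise GelSyntaxError(f"unexpected trailing {t}", t.line, t.col)
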