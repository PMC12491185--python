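"""Minimal PDF text extraction (and a tiny writer for synthetic fixtures).

Scope: born-digital PDFs whose page content streams use the standard text
operators (Tj, TJ, ') with literal strings and simple one-byte encodings,
optionally Flate-compressed. That covers programmatically generated
articles and most simple text-first PDFs; scanned pages, CID/Type0 fonts
and encrypted files are out of scope (encryption raises explicitly).

Streams are emitted in document object order, which matches reading order
for sequentially written files.
"""

from __future__ import annotations

import re
import zlib
from pathlib import Path

__all__ = ["PdfError", "EncryptedPdfError", "extract_pdf_text", "write_simple_pdf"]


class PdfError(ValueError):
    """Unreadable or structurally broken PDF."""


class EncryptedPdfError(PdfError):
    """The file declares an /Encrypt dictionary; extraction is unsupported."""


_STREAM_RE = re.compile(
    rb"<<(?P<dict>.*?)>>\s*stream\r?\n(?P<data>.*?)endstream", re.DOTALL
)

_ESCAPES = {
    b"n": "\n",
    b"r": "\r",
    b"t": "\t",
    b"b": "\b",
    b"f": "\f",
    b"(": "(",
    b")": ")",
    b"\\": "\\",
}


def _decode_literal(raw: bytes) -> str:
    """Decode the inside of a PDF literal string ( ... )."""
    out: list[str] = []
    i = 0
    while i < len(raw):
        c = raw[i : i + 1]
        if c == b"\\":
            nxt = raw[i + 1 : i + 2]
            if nxt.isdigit():  # octal escape, up to 3 digits
                j = i + 1
                while j < min(i + 4, len(raw)) and raw[j : j + 1].isdigit():
                    j += 1
                out.append(chr(int(raw[i + 1 : j], 8)))
                i = j
                continue
            out.append(_ESCAPES.get(nxt, nxt.decode("latin-1")))
            i += 2
        else:
            out.append(c.decode("latin-1"))
            i += 1
    return "".join(out)


def _iter_strings(content: bytes):
    """Yield text fragments from a content stream in operator order.

    Emits the decoded string for Tj / ' / TJ show operators and "\n" for the
    line-advance operators Td, TD, T*.
    """
    i = 0
    n = len(content)
    while i < n:
        c = content[i : i + 1]
        if c == b"(":
            # literal string: track nesting and escapes
            depth = 1
            j = i + 1
            start = j
            while j < n and depth:
                cj = content[j : j + 1]
                if cj == b"\\":
                    j += 2
                    continue
                if cj == b"(":
                    depth += 1
                elif cj == b")":
                    depth -= 1
                j += 1
            frag = content[start : j - 1]
            # find the operator that consumes this string
            tail = content[j : j + 8]
            if re.match(rb"\s*(Tj|')", tail):
                yield _decode_literal(frag)
            else:
                # inside a TJ array (or an operand we don't show); TJ arrays
                # are handled by yielding every literal they contain
                m = re.match(rb"[^\[\]()]*?\]\s*TJ", content[j : j + 200], re.DOTALL)
                if m or _in_tj_array(content, i):
                    yield _decode_literal(frag)
            i = j
        elif c == b"T":
            op = content[i : i + 2]
            if op in (b"Td", b"TD", b"T*"):
                yield "\n"
                i += 2
            else:
                i += 1
        else:
            i += 1


def _in_tj_array(content: bytes, pos: int) -> bool:
    """Is the string starting at ``pos`` inside a [ ... ] TJ array?"""
    open_br = content.rfind(b"[", 0, pos)
    if open_br == -1:
        return False
    close_br = content.rfind(b"]", 0, pos)
    return close_br < open_br


def extract_pdf_text(path: str | Path) -> str:
    """Extract the text of a PDF, pages/streams in document order.

    Raises :class:`EncryptedPdfError` for encrypted files and
    :class:`PdfError` for files that are not PDFs at all.
    """
    data = Path(path).read_bytes()
    if not data.lstrip()[:5].startswith(b"%PDF-"):
        raise PdfError(f"not a PDF file: {path}")
    if re.search(rb"/Encrypt\b", data):
        raise EncryptedPdfError(f"encrypted PDF not supported: {path}")
    pages: list[str] = []
    for m in _STREAM_RE.finditer(data):
        raw = m.group("data")
        if b"/FlateDecode" in m.group("dict"):
            try:
                raw = zlib.decompress(raw.rstrip(b"\r\n"))
            except zlib.error:
                continue  # image or unsupported stream; skip
        if b"BT" not in raw:
            continue
        text = "".join(_iter_strings(raw))
        text = re.sub(r"\n{2,}", "\n", text).strip("\n")
        if text:
            pages.append(text)
    return "\n\n".join(pages)


def _escape_literal(s: str) -> str:
    return s.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")


def write_simple_pdf(pages: list[list[str]], path: str | Path) -> Path:
    """Write a minimal single-font PDF: one entry per page, each a list of
    text lines. Intended for generating synthetic test articles."""
    objects: list[bytes] = []  # 1-indexed body objects, in object-number order
    n_pages = len(pages)
    kids = " ".join(f"{3 + 2 * i} 0 R" for i in range(n_pages))
    objects.append(b"<< /Type /Catalog /Pages 2 0 R >>")
    objects.append(
        f"<< /Type /Pages /Kids [{kids}] /Count {n_pages} >>".encode("latin-1")
    )
    font_obj = 3 + 2 * n_pages
    for i, lines in enumerate(pages):
        content_obj = 4 + 2 * i
        objects.append(
            (
                f"<< /Type /Page /Parent 2 0 R /MediaBox [0 0 612 792] "
                f"/Resources << /Font << /F1 {font_obj} 0 R >> >> "
                f"/Contents {content_obj} 0 R >>"
            ).encode("latin-1")
        )
        body = ["BT", "/F1 11 Tf", "72 720 Td"]
        for k, line in enumerate(lines):
            if k:
                body.append("0 -14 Td")
            body.append(f"({_escape_literal(line)}) Tj")
        body.append("ET")
        stream = "\n".join(body).encode("latin-1")
        objects.append(
            b"<< /Length %d >>\nstream\n%s\nendstream" % (len(stream), stream)
        )
    objects.append(
        b"<< /Type /Font /Subtype /Type1 /BaseFont /Helvetica >>"
    )

    out = bytearray(b"%PDF-1.4\n")
    offsets = [0]
    for num, obj in enumerate(objects, start=1):
        offsets.append(len(out))
        out += b"%d 0 obj\n" % num + obj + b"\nendobj\n"
    xref_at = len(out)
    out += b"xref\n0 %d\n" % (len(objects) + 1)
    out += b"0000000000 65535 f \n"
    for off in offsets[1:]:
        out += b"%010d 00000 n \n" % off
    out += (
        b"trailer\n<< /Size %d /Root 1 0 R >>\nstartxref\n%d\n%%%%EOF\n"
        % (len(objects) + 1, xref_at)
    )
    path = Path(path)
    path.write_bytes(bytes(out))
    return path
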