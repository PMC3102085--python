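"""Document and annotation data model: standoff I/O, BIO conversion, markup text extraction.

All offsets in this package are 0-based, half-open character offsets into the
owning :class:`SourceDocument`'s ``text``.  The invariant enforced everywhere
is offset fidelity: ``text[start:end] == surface`` for every token and entity.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree, html as lxml_html

__all__ = [
    "SourceDocument",
    "Token",
    "EntitySpan",
    "AnnotatedDocument",
    "IntegrityError",
    "BoundaryMismatch",
    "read_plain_text",
    "extract_text",
    "to_bio",
    "from_bio",
    "read_standoff",
    "write_standoff",
]

BIO_LABELS = ("O", "B-CM", "I-CM")

#: elements after which a single newline separates extracted text
_BLOCK_ELEMENTS = frozenset(
    {"p", "div", "li", "td", "th", "tr", "table", "ul", "ol", "br",
     "h1", "h2", "h3", "h4", "h5", "h6", "blockquote", "pre", "title", "body"}
)


class IntegrityError(ValueError):
    """A span's surface disagrees with the text slice it claims to cover."""


@dataclass(frozen=True)
class SourceDocument:
    """A source text with a stable identity; all annotation offsets index ``text``."""

    doc_id: str
    text: str
    origin: str = "plain"  # plain | xml | html


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad token offsets [{self.start}, {self.end})")
        if len(self.surface) != self.end - self.start:
            raise ValueError(
                f"token surface length {len(self.surface)} != span width "
                f"{self.end - self.start}"
            )


@dataclass
class EntitySpan:
    """A labelled character interval; ``CM`` is the chemical-mention class."""

    start: int
    end: int
    surface: str
    label: str = "CM"
    confidence: float | None = None
    provenance: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty entity span [{self.start}, {self.end})")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    def key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.label)


@dataclass
class AnnotatedDocument:
    document: SourceDocument
    entities: list[EntitySpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entities = sorted(self.entities, key=lambda e: (e.start, e.end))
        text = self.document.text
        for ent in self.entities:
            if ent.end > len(text):
                raise IntegrityError(
                    f"{self.document.doc_id}: span [{ent.start}, {ent.end}) "
                    f"beyond text length {len(text)}"
                )
            if text[ent.start:ent.end] != ent.surface:
                raise IntegrityError(
                    f"{self.document.doc_id}: surface {ent.surface!r} != text "
                    f"slice {text[ent.start:ent.end]!r} at [{ent.start}, {ent.end})"
                )


@dataclass(frozen=True)
class BoundaryMismatch:
    """Diagnostic for a gold entity whose boundary falls strictly inside a token.

    These entities cannot be expressed in a token-level BIO encoding and are
    dropped; counting them makes tokenisation noise observable.
    """

    entity: EntitySpan
    reason: str


def read_plain_text(path: str | Path, doc_id: str | None = None) -> SourceDocument:
    """Read a UTF-8 plain-text file; a leading BOM is stripped.

    Text is NFC-normalised at construction so downstream offsets always index
    a canonical string.  Undecodable bytes raise ``UnicodeDecodeError`` naming
    the byte offset.
    """
    path = Path(path)
    data = path.read_bytes()
    text = data.decode("utf-8-sig")
    text = unicodedata.normalize("NFC", text)
    return SourceDocument(doc_id=doc_id or path.stem, text=text, origin="plain")


def _markup_to_text(node, parts: list[str]) -> None:
    if node.text:
        parts.append(node.text)
    for child in node:
        if not isinstance(child.tag, str):  # comments, PIs
            if child.tail:
                parts.append(child.tail)
            continue
        _markup_to_text(child, parts)
        if child.tag.lower() in _BLOCK_ELEMENTS:
            parts.append("\n")
        if child.tail:
            parts.append(child.tail)


def extract_text_from_string(markup: str, origin: str = "xml") -> str:
    """Extract the text content of a markup string.

    Block-level elements (p, div, li, td, headings, br, ...) are separated by
    a single newline; inline markup introduces no break.  ``origin='xml'``
    requires well-formed XML and reports parse errors with line numbers;
    ``origin='html'`` is tolerant of fragments and malformed input.
    """
    if origin == "xml":
        try:
            root = etree.fromstring(markup.encode("utf-8"))
        except etree.XMLSyntaxError as exc:
            raise ValueError(f"XML parse error: {exc}") from exc
    elif origin == "html":
        root = lxml_html.fromstring(markup)
    else:
        raise ValueError(f"unknown markup origin {origin!r}")
    parts: list[str] = []
    _markup_to_text(root, parts)
    if isinstance(root.tag, str) and root.tag.lower() in _BLOCK_ELEMENTS:
        parts.append("\n")
    text = "".join(parts)
    # collapse runs of block separators; strip outer newlines/space
    out_lines = [ln.strip() for ln in text.split("\n")]
    text = "\n".join(ln for ln in out_lines if ln)
    return unicodedata.normalize("NFC", text)


def extract_text(path: str | Path, origin: str | None = None,
                 doc_id: str | None = None) -> SourceDocument:
    """Read an XML or HTML file and extract its text content.

    ``origin`` defaults from the file suffix (.xml -> xml, else html).
    """
    path = Path(path)
    if origin is None:
        origin = "xml" if path.suffix.lower() == ".xml" else "html"
    markup = path.read_bytes().decode("utf-8-sig")
    text = extract_text_from_string(markup, origin)
    return SourceDocument(doc_id=doc_id or path.stem, text=text, origin=origin)


def to_bio(tokens: list[Token], entities: list[EntitySpan]
           ) -> tuple[list[str], list[BoundaryMismatch]]:
    """Encode entities over a token sequence as BIO labels.

    Returns ``(labels, dropped)`` where each dropped entry records a gold
    entity whose start or end is not a token boundary — the partial-entity
    failure mode caused by tokenisation noise.  Such entities are excluded
    from the encoding rather than clipped.
    """
    start_index = {t.start: i for i, t in enumerate(tokens)}
    end_index = {t.end: i for i, t in enumerate(tokens)}
    labels = ["O"] * len(tokens)
    dropped: list[BoundaryMismatch] = []
    for ent in entities:
        i = start_index.get(ent.start)
        j = end_index.get(ent.end)
        if i is None or j is None or j < i:
            dropped.append(BoundaryMismatch(
                entity=ent,
                reason=f"boundary [{ent.start}, {ent.end}) not token-aligned",
            ))
            continue
        labels[i] = "B-CM"
        for k in range(i + 1, j + 1):
            labels[k] = "I-CM"
    return labels, dropped


def from_bio(tokens: list[Token], labels: list[str], text: str | None = None,
             label: str = "CM") -> tuple[list[EntitySpan], int]:
    """Decode BIO labels over tokens into entity spans.

    An ``I-CM`` following ``O`` or the sequence start is repaired to ``B-CM``;
    the number of repairs is returned alongside the entities.  ``text``, when
    given, supplies exact surfaces for multi-token entities (otherwise token
    surfaces are joined with single spaces).
    """
    if len(tokens) != len(labels):
        raise ValueError(f"{len(tokens)} tokens but {len(labels)} labels")
    entities: list[EntitySpan] = []
    repairs = 0
    run: list[Token] = []

    def flush() -> None:
        if not run:
            return
        start, end = run[0].start, run[-1].end
        surface = text[start:end] if text is not None else " ".join(
            t.surface for t in run)
        entities.append(EntitySpan(start=start, end=end, surface=surface,
                                   label=label))
        run.clear()

    for tok, lab in zip(tokens, labels):
        if lab == "B-CM":
            flush()
            run.append(tok)
        elif lab == "I-CM":
            if run:
                run.append(tok)
            else:  # orphan I: repair to B
                repairs += 1
                run.append(tok)
        else:
            if lab != "O":
                raise ValueError(f"unknown BIO label {lab!r}")
            flush()
    flush()
    return entities, repairs


# ---------------------------------------------------------------------------
# Standoff I/O: <doc_id>.txt holds the raw text, <doc_id>.ann holds
# tab-separated lines "id  label  start  end  surface[  confidence]".
# ---------------------------------------------------------------------------

def write_standoff(doc: SourceDocument, entities: list[EntitySpan],
                   directory: str | Path) -> tuple[Path, Path]:
    """Write a document/annotation file pair; returns the two paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    txt_path = directory / f"{doc.doc_id}.txt"
    ann_path = directory / f"{doc.doc_id}.ann"
    txt_path.write_text(doc.text, encoding="utf-8")
    lines = []
    for i, ent in enumerate(sorted(entities, key=lambda e: (e.start, e.end)), 1):
        if doc.text[ent.start:ent.end] != ent.surface:
            raise IntegrityError(
                f"{doc.doc_id}: refusing to write span T{i} "
                f"[{ent.start}, {ent.end}): surface mismatch")
        cols = [f"T{i}", ent.label, str(ent.start), str(ent.end), ent.surface]
        if ent.confidence is not None:
            cols.append(repr(ent.confidence))
        lines.append("\t".join(cols))
    ann_path.write_text("\n".join(lines) + ("\n" if lines else ""),
                        encoding="utf-8")
    return txt_path, ann_path


def read_standoff(path: str | Path) -> AnnotatedDocument:
    """Read a standoff pair; ``path`` may be the .txt, the .ann, or the bare stem.

    Every record is integrity-checked: offsets in bounds and surface equal to
    the text slice, otherwise :class:`IntegrityError` names the span.
    """
    path = Path(path)
    stem = path.with_suffix("") if path.suffix in {".txt", ".ann"} else path
    txt_path = stem.with_suffix(".txt")
    ann_path = stem.with_suffix(".ann")
    text = txt_path.read_bytes().decode("utf-8-sig")
    doc = SourceDocument(doc_id=stem.name, text=text, origin="plain")
    entities: list[EntitySpan] = []
    for lineno, line in enumerate(ann_path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) not in (5, 6):
            raise ValueError(f"{ann_path}:{lineno}: expected 5 or 6 columns, "
                             f"got {len(cols)}")
        span_id, label, start_s, end_s, surface = cols[:5]
        start, end = int(start_s), int(end_s)
        if end > len(text) or start < 0:
            raise IntegrityError(
                f"{ann_path}:{lineno}: span {span_id} [{start}, {end}) out of "
                f"bounds for text of length {len(text)}")
        if text[start:end] != surface:
            raise IntegrityError(
                f"{ann_path}:{lineno}: span {span_id} surface {surface!r} != "
                f"text slice {text[start:end]!r}")
        conf = float(cols[5]) if len(cols) == 6 else None
        entities.append(EntitySpan(start=start, end=end, surface=surface,
                                   label=label, confidence=conf))
    return AnnotatedDocument(document=doc, entities=entities)


def read_standoff_corpus(directory: str | Path) -> list[AnnotatedDocument]:
    """Read every standoff pair in a directory, sorted by doc_id."""
    directory = Path(directory)
    return [read_standoff(p) for p in sorted(directory.glob("*.txt"))]
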