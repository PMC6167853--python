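"""
Sequence file I/O: FASTA records and the GenBank feature table.

FASTA handling is by-the-byte faithful: a record is (header, sequence
text) and write -> read is the identity.  The GenBank side parses only the
FEATURES block of a flat file into :class:`SeqFeature` objects, keeping
the source conventions intact: 1-based inclusive coordinates, per-location
strand derived from ``complement(...)``, partial markers ``<`` / ``>``,
and an order-preserving qualifier multimap.  A renderer produces a
feature block that re-parses to the same features (fixed point), which is
what makes the parser testable without external files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "FastaRecord",
    "read_fasta",
    "write_fasta",
    "Location",
    "SeqFeature",
    "parse_genbank_features",
    "render_genbank_features",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@dataclass
class FastaRecord:
    header: str
    sequence_text: str

    def __post_init__(self):
        if "\n" in self.header or "\r" in self.header:
            raise ValueError("FASTA header must not contain line breaks")


def read_fasta(text: str) -> list[FastaRecord]:
    """Parse multi-record FASTA text; sequences may span multiple lines."""
    records: list[FastaRecord] = []
    header: str | None = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if header is not None:
                records.append(FastaRecord(header, "".join(chunks)))
            header = line[1:]
            chunks = []
        elif line.strip():
            if header is None:
                raise ValueError("Sequence data before first FASTA header")
            chunks.append(line.strip())
    if header is not None:
        records.append(FastaRecord(header, "".join(chunks)))
    return records


def write_fasta(records, line_width: int = 80) -> str:
    """Serialize records to FASTA text, wrapping sequence lines."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    lines: list[str] = []
    for rec in records:
        if "\n" in rec.header or "\r" in rec.header:
            raise ValueError("FASTA header must not contain line breaks")
        lines.append(">" + rec.header)
        seq = rec.sequence_text
        for i in range(0, len(seq), line_width):
            lines.append(seq[i : i + line_width])
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# GenBank feature table
# ---------------------------------------------------------------------------

# INSDC flat-file layout: feature keys start at column 6 (0-based 5),
# locations/qualifiers at column 22 (0-based 21).
_KEY_INDENT = 5
_QUAL_INDENT = 21

# Qualifiers whose multi-line values are sequence-like and joined without
# a separator; all others are joined with a single space.
_NO_SPACE_JOIN = {"translation", "peptide", "anticodon"}


@dataclass
class Location:
    """
    One contiguous span on the reference sequence, 1-based inclusive.

    ``between`` marks a site between two bases (``n^m`` notation);
    ``partial_start`` / ``partial_end`` carry the ``<`` / ``>`` markers.
    """

    first: int
    last: int
    strand: str = "+"
    partial_start: bool = False
    partial_end: bool = False
    between: bool = False

    def __post_init__(self):
        if self.first > self.last:
            raise ValueError(
                f"Location first ({self.first}) exceeds last ({self.last})"
            )
        if self.strand not in "+-":
            raise ValueError(f"Invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.last - self.first + 1

    def span0(self) -> tuple[int, int]:
        """The span as a 0-based half-open interval."""
        return self.first - 1, self.last


@dataclass
class SeqFeature:
    """A feature-table entry: key, locations and ordered qualifiers."""

    key: str
    locations: list = field(default_factory=list)
    qualifiers: list = field(default_factory=list)  # (name, value-or-None)

    def __post_init__(self):
        if not self.locations:
            raise ValueError(f"Feature {self.key!r} has no location")
        for name, _ in self.qualifiers:
            if not name:
                raise ValueError("Qualifier names must be non-empty")

    def qualifier(self, name: str):
        """First value of the named qualifier (None for bare qualifiers)."""
        for qname, value in self.qualifiers:
            if qname == name:
                return value
        raise KeyError(name)

    def has_qualifier(self, name: str) -> bool:
        return any(qname == name for qname, _ in self.qualifiers)


class GenBankParseError(ValueError):
    pass


def _parse_span(token: str, strand: str, context: str) -> Location:
    partial_start = partial_end = False
    between = False
    if ".." in token:
        left, right = token.split("..", 1)
        sep = ".."
    elif "^" in token:
        left, right = token.split("^", 1)
        between = True
        sep = "^"
    else:
        left = right = token
        sep = None
    del sep
    if left.startswith("<"):
        partial_start = True
        left = left[1:]
    if right.startswith(">"):
        partial_end = True
        right = right[1:]
    try:
        first, last = int(left), int(right)
    except ValueError:
        raise GenBankParseError(
            f"Malformed location {token!r} in {context}"
        ) from None
    # On the minus strand the written < / > markers still refer to the
    # numerically lower/higher end; keep them positional.
    return Location(first, last, strand, partial_start, partial_end, between)


def _split_args(inner: str, context: str) -> list[str]:
    parts, depth, start = [], 0, 0
    for i, ch in enumerate(inner):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise GenBankParseError(f"Unbalanced parentheses in {context}")
        elif ch == "," and depth == 0:
            parts.append(inner[start:i])
            start = i + 1
    if depth != 0:
        raise GenBankParseError(f"Unbalanced parentheses in {context}")
    parts.append(inner[start:])
    return [p.strip() for p in parts if p.strip()]


def _parse_location(text: str, strand: str, context: str) -> list[Location]:
    text = text.strip()
    if text.count("(") != text.count(")"):
        raise GenBankParseError(f"Unbalanced parentheses in {context}")
    for op in ("complement", "join", "order"):
        if text.startswith(op + "(") and text.endswith(")"):
            inner = text[len(op) + 1 : -1]
            if op == "complement":
                flipped = "-" if strand == "+" else "+"
                # complement(join(a,b)) keeps written order
                return _parse_location(inner, flipped, context)
            locs: list[Location] = []
            for arg in _split_args(inner, context):
                locs.extend(_parse_location(arg, strand, context))
            return locs
    return [_parse_span(text, strand, context)]


def _render_location(locations) -> str:
    def one(loc: Location) -> str:
        left = ("<" if loc.partial_start else "") + str(loc.first)
        right = (">" if loc.partial_end else "") + str(loc.last)
        if loc.first == loc.last and not (
            loc.partial_start or loc.partial_end or loc.between
        ):
            body = str(loc.first)
        elif loc.between:
            body = f"{left}^{right}"
        else:
            body = f"{left}..{right}"
        return f"complement({body})" if loc.strand == "-" else body

    rendered = [one(loc) for loc in locations]
    if len(rendered) == 1:
        return rendered[0]
    return "join(" + ",".join(rendered) + ")"


def _parse_qualifier_block(lines: list[str], feature_key: str):
    """Split continuation lines of a feature into qualifier entries."""
    qualifiers = []
    i = 0
    while i < len(lines):
        line = lines[i]
        if not line.startswith("/"):
            raise GenBankParseError(
                f"Expected qualifier line in feature {feature_key!r}: {line!r}"
            )
        if "=" not in line:
            qualifiers.append((line[1:], None))
            i += 1
            continue
        name, value = line[1:].split("=", 1)
        if value.startswith('"'):
            parts = [value[1:]]
            # collect until the closing quote
            while not parts[-1].endswith('"'):
                i += 1
                if i >= len(lines):
                    raise GenBankParseError(
                        f"Unterminated quoted value for /{name} in feature "
                        f"{feature_key!r}"
                    )
                parts.append(lines[i])
            parts[-1] = parts[-1][:-1]
            joiner = "" if name in _NO_SPACE_JOIN else " "
            qualifiers.append((name, joiner.join(parts)))
        else:
            qualifiers.append((name, value))
        i += 1
    return qualifiers


def parse_genbank_features(text: str) -> list[SeqFeature]:
    """
    Parse the FEATURES block of GenBank flat-file text into
    :class:`SeqFeature` objects.  Only the feature table is read; any
    other blocks (LOCUS, ORIGIN, ...) are ignored.
    """
    lines = text.splitlines()
    try:
        start = next(
            i for i, ln in enumerate(lines) if ln.startswith("FEATURES")
        )
    except StopIteration:
        raise GenBankParseError("No FEATURES block found") from None

    entries: list[tuple[str, int, list[str]]] = []  # key, lineno, content
    for lineno in range(start + 1, len(lines)):
        line = lines[lineno]
        if not line.strip():
            continue
        if not line.startswith(" "):  # next top-level keyword (ORIGIN, ...)
            break
        stripped = line[:_QUAL_INDENT]
        content = line[_QUAL_INDENT:].strip()
        key = stripped.strip()
        if key:
            entries.append((key, lineno + 1, [content] if content else []))
        else:
            if not entries:
                raise GenBankParseError(
                    f"Continuation line before first feature (line {lineno + 1})"
                )
            entries[-1][2].append(content)

    features: list[SeqFeature] = []
    for key, lineno, content in entries:
        # location may wrap across lines until the first qualifier line
        loc_parts: list[str] = []
        qual_lines: list[str] = []
        for part in content:
            if part.startswith("/") or qual_lines:
                qual_lines.append(part)
            else:
                loc_parts.append(part)
        context = f"feature {key!r} (line {lineno})"
        if not loc_parts:
            raise GenBankParseError(f"Missing location in {context}")
        locations = _parse_location("".join(loc_parts), "+", context)
        qualifiers = _parse_qualifier_block(qual_lines, key)
        features.append(SeqFeature(key, locations, qualifiers))
    return features


def render_genbank_features(features, line_width: int = 79) -> str:
    """
    Serialize features back into a FEATURES block.
    ``parse_genbank_features(render_genbank_features(f)) == f``.
    """
    out = ["FEATURES             Location/Qualifiers"]
    indent = " " * _QUAL_INDENT
    for feat in features:
        head = " " * _KEY_INDENT + feat.key
        head = head.ljust(_QUAL_INDENT)[:_QUAL_INDENT]
        if len(feat.key) + _KEY_INDENT > _QUAL_INDENT - 1:
            raise ValueError(f"Feature key too long: {feat.key!r}")
        out.append(head + _render_location(feat.locations))
        for name, value in feat.qualifiers:
            if value is None:
                out.append(f"{indent}/{name}")
                continue
            text = f'/{name}="{value}"'
            avail = line_width - _QUAL_INDENT
            if len(text) <= avail:
                out.append(indent + text)
            elif name in _NO_SPACE_JOIN:
                # sequence-like values re-join without separator: break anywhere
                for i in range(0, len(text), avail):
                    out.append(indent + text[i : i + avail])
            else:
                # prose values re-join with one space: break only at spaces
                rest = text
                while len(rest) > avail:
                    cut = rest.rfind(" ", 1, avail + 1)
                    if cut < 0:
                        cut = avail  # overlong word; mid-word break
                        out.append(indent + rest[:cut])
                        rest = rest[cut:]
                    else:
                        out.append(indent + rest[:cut])
                        rest = rest[cut + 1 :]
                out.append(indent + rest)
    return "\n".join(out) + "\n"
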