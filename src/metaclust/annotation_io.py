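"""GFF3/GTF parsing: extract the coordinates of all features of one type."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')

VALID_STRANDS = frozenset({"+", "-", "."})


class AnnotationError(Exception):
    """Fatal annotation-stage failure (unreadable file, no matching features)."""


@dataclass(frozen=True)
class GenomicFeature:
    """One annotated locus. Coordinates are 1-based inclusive, as in GFF/GTF."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_type: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid coordinates for {self.id!r}: start={self.start} end={self.end}"
            )
        if not self.id:
            raise ValueError("feature id must be non-empty")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} for {self.id!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _resolve_id(attributes: str, chrom: str, start: int, end: int) -> str:
    """Pick a locus name from the 9th column.

    `key=value` pairs mean GFF3: prefer ID, then Name, then gene_id.
    `key "value";` pairs mean GTF: use gene_id.  When nothing resolves the
    id is synthesized as ``chrom:start-end``.
    """
    attributes = attributes.strip()
    if "=" in attributes:
        pairs = {}
        for field in attributes.split(";"):
            field = field.strip()
            if not field or "=" not in field:
                continue
            key, _, value = field.partition("=")
            pairs[key.strip()] = value.strip()
        for key in ("ID", "Name", "gene_id"):
            if pairs.get(key):
                return pairs[key]
    elif '"' in attributes:
        pairs = dict(_GTF_ATTR.findall(attributes))
        if pairs.get("gene_id"):
            return pairs["gene_id"]
    return f"{chrom}:{start}-{end}"


def _deduplicate(ids: list[str]) -> list[str]:
    """Suffix repeated ids with .2, .3, ... in order of appearance."""
    seen: dict[str, int] = {}
    out = []
    for name in ids:
        count = seen.get(name, 0) + 1
        seen[name] = count
        if count == 1:
            out.append(name)
        else:
            logger.warning("duplicate feature id %r renamed to %r", name, f"{name}.{count}")
            out.append(f"{name}.{count}")
    return out


def parse_annotation(path: str | Path, feature_type: str) -> list[GenomicFeature]:
    """Return every record of `feature_type` from a GFF3 or GTF file.

    Coordinates are taken verbatim from columns 4-5 (1-based inclusive) and
    order of appearance is preserved.  Malformed lines are skipped with a
    logged warning; zero matching features is a fatal error.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise AnnotationError(f"cannot read annotation file {path}: {exc}") from exc

    raw: list[tuple[str, str, int, int, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            logger.warning("line %d: fewer than 8 tab-separated columns, skipped", lineno)
            continue
        if cols[2] != feature_type:
            continue
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            logger.warning("line %d: non-integer coordinates, skipped", lineno)
            continue
        if not (1 <= start <= end):
            logger.warning("line %d: invalid interval %d-%d, skipped", lineno, start, end)
            continue
        strand = cols[6] if cols[6] in VALID_STRANDS else "."
        attributes = cols[8] if len(cols) > 8 else ""
        raw.append((cols[0], strand, start, end, attributes))

    if not raw:
        raise AnnotationError(f"no features of type {feature_type!r} in {path}")

    ids = _deduplicate(
        [_resolve_id(attrs, chrom, start, end) for chrom, _, start, end, attrs in raw]
    )
    features = [
        GenomicFeature(
            id=name, chrom=chrom, start=start, end=end, strand=strand,
            feature_type=feature_type,
        )
        for name, (chrom, strand, start, end, _) in zip(ids, raw)
    ]
    logger.info("parsed %d features of type %r from %s", len(features), feature_type, path)
    return features
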