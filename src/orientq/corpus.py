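"""Audit-corpus data model and I/O.

An :class:`AuditCorpus` holds free-text environmental audit records, one or
more per institution.  Records typically originate from a multimodal model
that describes facility images against a fixed indicator catalogue; this
module only defines the adapter contract for that step — it never performs
any network or model call itself.

The canonical interchange format is JSONL (one record per line, keys
``institution_id``, ``record_id``, ``text``, optional ``tags``).  CSV with
the same header is supported for convenience; tags are ``;``-joined there.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import yaml

from .errors import EmptyCorpusError, SchemaError

_WS = re.compile(r"\s+")

REQUIRED_FIELDS = ("institution_id", "record_id", "text")


def normalize_whitespace(text: str) -> str:
    """Collapse whitespace runs and strip the ends; no other mutation."""
    return _WS.sub(" ", text).strip()


@dataclass(frozen=True)
class AuditRecord:
    """One free-text audit of one image (or document) of an institution."""

    institution_id: str
    record_id: str
    text: str
    dimension_tags: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "text", normalize_whitespace(self.text))
        object.__setattr__(self, "dimension_tags", tuple(self.dimension_tags))
        if not self.institution_id:
            raise SchemaError("institution_id must be non-empty")
        if not self.record_id:
            raise SchemaError("record_id must be non-empty")
        if not self.text:
            raise SchemaError(
                f"record ({self.institution_id}, {self.record_id}): "
                "text empty after whitespace normalization"
            )


class AuditCorpus:
    """Ordered collection of audit records indexed by institution.

    Invariants: every ``(institution_id, record_id)`` pair is unique and
    every institution has at least one record.
    """

    def __init__(self, records: Iterable[AuditRecord]):
        self.records: list[AuditRecord] = list(records)
        if not self.records:
            raise EmptyCorpusError("corpus has no records")
        self.institutions: dict[str, list[AuditRecord]] = {}
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.institution_id, rec.record_id)
            if key in seen:
                raise SchemaError(f"duplicate (institution_id, record_id): {key}")
            seen.add(key)
            self.institutions.setdefault(rec.institution_id, []).append(rec)

    @property
    def n_institutions(self) -> int:
        return len(self.institutions)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def institution_ids(self) -> list[str]:
        return list(self.institutions)

    def __eq__(self, other) -> bool:
        return isinstance(other, AuditCorpus) and self.records == other.records

    def __repr__(self) -> str:
        return (
            f"AuditCorpus(n_institutions={self.n_institutions}, "
            f"n_records={self.n_records})"
        )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("jsonl", "csv"):
        return suffix
    raise SchemaError(f"cannot infer format from suffix of {path}")


def read_corpus(path: str | Path, format: str | None = None) -> AuditCorpus:
    """Read a corpus from JSONL or CSV; row order is preserved."""
    path = Path(path)
    fmt = _infer_format(path, format)
    records: list[AuditRecord] = []
    if fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
                records.append(_record_from_mapping(obj, f"{path}:{lineno}"))
    elif fmt == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise EmptyCorpusError(f"{path}: empty CSV file")
            for field_name in REQUIRED_FIELDS:
                if field_name not in reader.fieldnames:
                    raise SchemaError(f"{path}: missing required column '{field_name}'")
            for lineno, row in enumerate(reader, 2):
                tags = row.get("tags") or ""
                obj = {
                    "institution_id": row.get("institution_id"),
                    "record_id": row.get("record_id"),
                    "text": row.get("text"),
                    "tags": [t for t in tags.split(";") if t],
                }
                records.append(_record_from_mapping(obj, f"{path}:{lineno}"))
    else:
        raise SchemaError(f"unknown corpus format: {fmt!r}")
    if not records:
        raise EmptyCorpusError(f"{path}: no records")
    return AuditCorpus(records)


def _record_from_mapping(obj: dict, where: str) -> AuditRecord:
    for field_name in REQUIRED_FIELDS:
        value = obj.get(field_name)
        if value is None or value == "":
            raise SchemaError(f"{where}: missing required field '{field_name}'")
    return AuditRecord(
        institution_id=str(obj["institution_id"]),
        record_id=str(obj["record_id"]),
        text=str(obj["text"]),
        dimension_tags=tuple(obj.get("tags") or ()),
    )


def write_corpus(corpus: AuditCorpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus so that :func:`read_corpus` returns an equal corpus."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in corpus.records:
                fh.write(
                    json.dumps(
                        {
                            "institution_id": rec.institution_id,
                            "record_id": rec.record_id,
                            "text": rec.text,
                            "tags": list(rec.dimension_tags),
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    elif fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["institution_id", "record_id", "text", "tags"])
            for rec in corpus.records:
                writer.writerow(
                    [rec.institution_id, rec.record_id, rec.text, ";".join(rec.dimension_tags)]
                )
    else:
        raise SchemaError(f"unknown corpus format: {fmt!r}")


# --------------------------------------------------------------------------
# Indicator catalogue and the external-auditor adapter contract
# --------------------------------------------------------------------------

VALID_GROUPS = ("indoor", "outdoor", "free")


@dataclass(frozen=True)
class Dimension:
    group: str
    name: str
    indicators: str


@dataclass
class DimensionCatalogue:
    """The audit indicator catalogue used to prompt an external auditor.

    Grouped into indoor, outdoor and a free dimension for salient features
    not covered by the named indicators.
    """

    dimensions: list[Dimension] = field(default_factory=list)

    def __post_init__(self):
        names = [d.name for d in self.dimensions]
        if len(set(names)) != len(names):
            raise SchemaError("dimension names must be unique")
        for d in self.dimensions:
            if d.group not in VALID_GROUPS:
                raise SchemaError(f"unknown dimension group: {d.group!r}")

    def names(self) -> list[str]:
        return [d.name for d in self.dimensions]

    def by_group(self, group: str) -> list[Dimension]:
        return [d for d in self.dimensions if d.group == group]


def load_catalogue(path: str | Path | None = None) -> DimensionCatalogue:
    """Load the indicator catalogue; defaults to the one shipped in package data."""
    if path is None:
        path = Path(__file__).parent / "data" / "dimension_catalogue.yaml"
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    dims = [
        Dimension(group=d["group"], name=d["name"], indicators=d["indicators"])
        for d in raw["dimensions"]
    ]
    return DimensionCatalogue(dims)


def render_audit_prompt(catalogue: DimensionCatalogue) -> str:
    """Render the catalogue as an instruction template for an external
    image auditor (human or multimodal model)."""
    lines = [
        "Audit the facility image objectively against the following "
        "dimensions. Describe only what is visible; one plain sentence per "
        "observed feature; do not speculate.",
        "",
    ]
    for group in VALID_GROUPS:
        dims = catalogue.by_group(group)
        if not dims:
            continue
        lines.append(f"[{group} dimensions]")
        for i, d in enumerate(dims, 1):
            lines.append(f"{i}. {d.name}: {d.indicators}")
        lines.append("")
    return "\n".join(lines).strip() + "\n"


#: Adapter contract: given an opaque image reference and the catalogue,
#: return the audit text for that image.  Implementations live outside the
#: core package (no network code here).
AuditTextAdapter = Callable[[str, DimensionCatalogue], str]


def build_corpus_with_adapter(
    items: Sequence[tuple[str, str, str]],
    adapter: AuditTextAdapter,
    catalogue: DimensionCatalogue,
) -> AuditCorpus:
    """Run an external audit adapter over ``(institution_id, record_id,
    image_ref)`` items and assemble the resulting corpus."""
    records = [
        AuditRecord(institution_id=inst, record_id=rec, text=adapter(ref, catalogue))
        for inst, rec, ref in items
    ]
    return AuditCorpus(records)
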