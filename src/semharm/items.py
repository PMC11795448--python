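"""Questionnaire item metadata: reading, validation, and canonical export.

An *item* is one question inside an *instrument* (a standardized
questionnaire such as AUDIT or NEO-FFI).  The only hard requirements on an
input table are an instrument column and a text column; study label,
variable name and language code are optional extras that help a human
reviewer trace a match back to its source dataset.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, EmptyInputError

#: Canonical column order of the items CSV written by :func:`write_items`.
CANONICAL_COLUMNS = ("item_id", "study", "instrument", "variable", "text", "language")

_WS = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Trim surrounding whitespace and collapse internal runs to one space.

    Case is preserved: capitalization may carry meaning for embedding
    models, so cleaning is kept minimal and reversible.
    """
    return _WS.sub(" ", str(text)).strip()


@dataclass(frozen=True)
class Item:
    """One questionnaire item."""

    item_id: str
    instrument: str
    text: str
    study: str = ""
    variable: str = ""
    language: str = "und"

    def __post_init__(self) -> None:
        if not str(self.instrument).strip():
            raise ValueError(f"item {self.item_id!r}: instrument must be non-empty")
        if not normalize_text(self.text):
            raise ValueError(f"item {self.item_id!r}: text must be non-empty")


class ItemSet:
    """Ordered collection of :class:`Item` with unique ids.

    Input order is preserved so that row indices remain meaningful, and
    instrument grouping is always recoverable from the per-item labels.
    """

    def __init__(self, items: Sequence[Item], provenance: Mapping | None = None):
        items = list(items)
        if not items:
            raise EmptyInputError("ItemSet requires at least one item")
        ids = [it.item_id for it in items]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise ValueError(f"duplicate item_id(s): {dup[:5]}")
        self._items = items
        self._index = {it.item_id: i for i, it in enumerate(items)}
        self.provenance = dict(provenance or {})

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[Item]:
        return iter(self._items)

    def __getitem__(self, item_id: str) -> Item:
        return self._items[self._index[item_id]]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self._items]

    @property
    def texts(self) -> list[str]:
        return [it.text for it in self._items]

    def instrument_of(self, item_id: str) -> str:
        return self[item_id].instrument

    def instruments(self) -> list[str]:
        """Distinct instrument labels in first-appearance order."""
        seen: dict[str, None] = {}
        for it in self._items:
            seen.setdefault(it.instrument, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "item_id": it.item_id,
                    "study": it.study,
                    "instrument": it.instrument,
                    "variable": it.variable,
                    "text": it.text,
                    "language": it.language,
                }
                for it in self._items
            ],
            columns=list(CANONICAL_COLUMNS),
        )


@dataclass
class ValidationReport:
    """Report-only summary of an :class:`ItemSet`; never mutates input."""

    n_items: int
    per_instrument: dict[str, int]
    duplicate_texts: list[tuple[str, str, int]] = field(default_factory=list)
    language_tally: dict[str, int] = field(default_factory=dict)

    @property
    def n_warnings(self) -> int:
        return len(self.duplicate_texts)


REQUIRED_ROLES = ("instrument", "text")
OPTIONAL_ROLES = ("study", "variable", "language", "item_id")


def load_item_table(
    path: str | Path,
    column_map: Mapping[str, str],
    format: str | None = None,
) -> ItemSet:
    """Read an item table from CSV (UTF-8) or XLSX into an :class:`ItemSet`.

    Parameters
    ----------
    path:
        Input file.  ``format`` defaults to the file suffix.
    column_map:
        Maps roles to column names.  Roles ``instrument`` and ``text`` are
        required; ``study``, ``variable``, ``language`` and ``item_id``
        optional.

    Rows with empty text (after whitespace normalization) are dropped; the
    dropped count is recorded in ``ItemSet.provenance['n_dropped']``.  When
    no ``variable`` role is mapped, ids take the stable form
    ``"<instrument>#<row-index>"``.
    """
    path = Path(path)
    for role in REQUIRED_ROLES:
        if role not in column_map:
            raise ConfigurationError(f"column_map is missing required role {role!r}")
    unknown = set(column_map) - set(REQUIRED_ROLES) - set(OPTIONAL_ROLES)
    if unknown:
        raise ConfigurationError(f"unknown column roles: {sorted(unknown)}")

    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        table = pd.read_csv(path, encoding="utf-8", dtype=str, keep_default_na=False)
    elif fmt == "xlsx":
        table = pd.read_excel(path, dtype=str, engine="openpyxl").fillna("")
    else:
        raise ConfigurationError(f"unsupported format {fmt!r} (expected csv or xlsx)")

    missing = [c for c in column_map.values() if c not in table.columns]
    if missing:
        raise ConfigurationError(
            f"column(s) {missing} named in column_map not present in {path.name}"
        )

    items: list[Item] = []
    n_dropped = 0
    for row_index, row in enumerate(table.itertuples(index=False)):
        rec = dict(zip(table.columns, row))
        text = normalize_text(rec[column_map["text"]])
        if not text:
            n_dropped += 1
            continue
        instrument = normalize_text(rec[column_map["instrument"]])
        variable = normalize_text(rec.get(column_map.get("variable", ""), ""))
        if "item_id" in column_map:
            item_id = normalize_text(rec[column_map["item_id"]])
        elif variable:
            item_id = f"{instrument}#{variable}"
        else:
            item_id = f"{instrument}#{row_index}"
        items.append(
            Item(
                item_id=item_id,
                instrument=instrument,
                text=text,
                study=normalize_text(rec.get(column_map.get("study", ""), "")),
                variable=variable,
                language=normalize_text(rec.get(column_map.get("language", ""), ""))
                or "und",
            )
        )
    if not items:
        raise EmptyInputError(f"{path.name}: no rows with non-empty text")
    return ItemSet(
        items,
        provenance={
            "path": str(path),
            "column_map": dict(column_map),
            "n_dropped": n_dropped,
        },
    )


def write_items(items: ItemSet, path: str | Path) -> Path:
    """Write the canonical items CSV (fixed column order, UTF-8)."""
    path = Path(path)
    items.to_frame().to_csv(path, index=False, encoding="utf-8")
    return path


def validate_items(items: ItemSet) -> ValidationReport:
    """Summarize an ItemSet: per-instrument counts, duplicate texts, languages."""
    frame = items.to_frame()
    per_instrument = frame.groupby("instrument", sort=False)["item_id"].count().to_dict()
    duplicates = [
        (instrument, text, int(count))
        for (instrument, text), count in frame.groupby(["instrument", "text"], sort=False)[
            "item_id"
        ]
        .count()
        .items()
        if count > 1
    ]
    language_tally = frame.groupby("language", sort=False)["item_id"].count().to_dict()
    return ValidationReport(
        n_items=len(items),
        per_instrument={k: int(v) for k, v in per_instrument.items()},
        duplicate_texts=duplicates,
        language_tally={k: int(v) for k, v in language_tally.items()},
    )
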