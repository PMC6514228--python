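"""Graded-response-model item banks.

An item bank is an ordered collection of calibrated polytomous items, each
with a logistic discrimination (slope) ``a`` and four strictly ordered
threshold locations ``b1 < b2 < b3 < b4`` on the latent-trait (theta) scale.
Items carry provenance metadata: the source questionnaire they were drawn
from and the internet-addiction symptom domain they measure.

The 59-item CAT-IA bank is shipped as packaged data and loaded with
:func:`load_packaged_bank`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "SOURCE_SCALES",
    "DOMAINS",
    "ItemRecord",
    "ItemBank",
    "BankValidationError",
    "read_item_bank",
    "write_item_bank",
    "bank_summary",
    "load_packaged_bank",
    "PACKAGED_BANK_FILENAME",
]

#: The four source questionnaires contributing items to the pool.
SOURCE_SCALES = ("IAT", "GPIUS", "GAS", "CIAT")

#: The seven-domain internet-addiction symptom taxonomy.
DOMAINS = (
    "salience",
    "tolerance",
    "mood modification",
    "relapse",
    "withdrawal",
    "negative outcomes",
    "benefits",
)

PACKAGED_BANK_FILENAME = "cat_ia_bank_59.csv"

_CSV_COLUMNS = ["item_id", "source_scale", "domain", "label", "a", "b1", "b2", "b3", "b4"]


class BankValidationError(ValueError):
    """An item bank violates a structural invariant."""


@dataclass(frozen=True)
class ItemRecord:
    """A single graded-response item.

    Parameters
    ----------
    item_id : str
        Unique identifier, e.g. ``"CIAT-81"``.
    source_scale : str
        One of :data:`SOURCE_SCALES`.
    domain : str
        One of :data:`DOMAINS`.
    label : str
        Abbreviated item wording.
    a : float
        Discrimination (logistic slope), strictly positive.
    b : tuple of float
        Four strictly increasing category thresholds ``(b1, b2, b3, b4)``.
    """

    item_id: str
    source_scale: str
    domain: str
    label: str
    a: float
    b: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.source_scale not in SOURCE_SCALES:
            raise BankValidationError(
                f"item {self.item_id!r}: unknown source scale {self.source_scale!r}"
            )
        if self.domain not in DOMAINS:
            raise BankValidationError(
                f"item {self.item_id!r}: unknown domain {self.domain!r}"
            )
        if not (np.isfinite(self.a) and self.a > 0):
            raise BankValidationError(
                f"item {self.item_id!r}: discrimination a={self.a} must be > 0"
            )
        b = tuple(float(x) for x in self.b)
        if len(b) != 4 or not all(np.isfinite(b)):
            raise BankValidationError(
                f"item {self.item_id!r}: expected 4 finite thresholds, got {self.b!r}"
            )
        if not (b[0] < b[1] < b[2] < b[3]):
            raise BankValidationError(
                f"item {self.item_id!r}: thresholds must satisfy b1 < b2 < b3 < b4, got {b}"
            )
        object.__setattr__(self, "b", b)


@dataclass(frozen=True)
class ItemBank:
    """An ordered, validated collection of :class:`ItemRecord`.

    Responses to every item use five ordered categories (scored 1-5 in
    files, 0-4 internally).
    """

    items: tuple[ItemRecord, ...]
    n_categories: int = 5

    def __post_init__(self) -> None:
        items = tuple(self.items)
        if not items:
            raise BankValidationError("empty bank")
        ids = [it.item_id for it in items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise BankValidationError(f"duplicate item_id(s): {sorted(dupes)}")
        object.__setattr__(self, "items", items)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ItemRecord]:
        return iter(self.items)

    def __getitem__(self, item_id: str) -> ItemRecord:
        try:
            return self._index[item_id]
        except KeyError:
            raise KeyError(f"item {item_id!r} not in bank") from None

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def _index(self) -> dict[str, ItemRecord]:
        return {it.item_id: it for it in self.items}

    # -- parameter arrays used by the GRM engine ------------------------------
    @property
    def a_values(self) -> np.ndarray:
        """Discriminations, shape (n_items,)."""
        return np.array([it.a for it in self.items], dtype=float)

    @property
    def b_values(self) -> np.ndarray:
        """Thresholds, shape (n_items, 4)."""
        return np.array([it.b for it in self.items], dtype=float)

    def subset(self, item_ids: Iterable[str]) -> "ItemBank":
        """A new bank restricted to ``item_ids``, preserving bank order."""
        keep = set(item_ids)
        missing = keep - set(self.item_ids)
        if missing:
            raise KeyError(f"item(s) not in bank: {sorted(missing)}")
        return ItemBank(
            tuple(it for it in self.items if it.item_id in keep), self.n_categories
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "item_id": it.item_id,
                "source_scale": it.source_scale,
                "domain": it.domain,
                "label": it.label,
                "a": it.a,
                "b1": it.b[0],
                "b2": it.b[1],
                "b3": it.b[2],
                "b4": it.b[3],
            }
            for it in self.items
        ]
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def _bank_from_frame(df: pd.DataFrame, source: str) -> ItemBank:
    missing = [c for c in _CSV_COLUMNS if c not in df.columns and c != "label"]
    if missing:
        raise BankValidationError(f"{source}: missing column(s) {missing}")
    if len(df) == 0:
        raise BankValidationError(f"{source}: empty bank (no data rows)")
    items = []
    for i, row in df.iterrows():
        try:
            params = [float(row[c]) for c in ("a", "b1", "b2", "b3", "b4")]
        except (TypeError, ValueError) as exc:
            raise BankValidationError(
                f"{source}: malformed row {i + 2} (item_id={row.get('item_id')!r}): {exc}"
            ) from None
        items.append(
            ItemRecord(
                item_id=str(row["item_id"]),
                source_scale=str(row["source_scale"]),
                domain=str(row["domain"]),
                label=str(row.get("label", "")),
                a=params[0],
                b=tuple(params[1:]),  # type: ignore[arg-type]
            )
        )
    return ItemBank(tuple(items))


def read_item_bank(path: str | Path) -> ItemBank:
    """Read a validated item bank from a CSV file.

    The file must be UTF-8 CSV with header columns ``item_id, source_scale,
    domain, label, a, b1, b2, b3, b4``. Every structural invariant (ordered
    thresholds, positive discrimination, closed vocabularies, unique ids) is
    checked; violations raise :class:`BankValidationError` naming the item.
    """
    path = Path(path)
    df = pd.read_csv(path)
    return _bank_from_frame(df, str(path))


def write_item_bank(bank: ItemBank, path: str | Path) -> None:
    """Write ``bank`` to CSV at 3-decimal printed precision.

    ``read_item_bank(write_item_bank(bank))`` round-trips the parameter
    fields exactly for parameters stated at 3 decimals.
    """
    df = bank.to_frame()
    for c in ("a", "b1", "b2", "b3", "b4"):
        df[c] = df[c].map(lambda x: f"{x:.3f}")
    df.to_csv(path, index=False)


def load_packaged_bank() -> ItemBank:
    """Load the packaged 59-item CAT-IA bank."""
    data = resources.files("catia").joinpath("data", PACKAGED_BANK_FILENAME).read_text()
    return _bank_from_frame(pd.read_csv(io.StringIO(data)), PACKAGED_BANK_FILENAME)


def bank_summary(bank: ItemBank) -> dict:
    """Summary statistics of an item bank.

    Returns a dict with the number of items, mean/SD of discrimination,
    min/max of each threshold, and counts per domain and per source scale
    (each summing to the bank size).
    """
    a = bank.a_values
    b = bank.b_values
    domains = [it.domain for it in bank]
    scales = [it.source_scale for it in bank]
    return {
        "n_items": len(bank),
        "a_mean": float(a.mean()),
        "a_sd": float(a.std(ddof=1)) if len(bank) > 1 else 0.0,
        "b_min": {f"b{k + 1}": float(b[:, k].min()) for k in range(4)},
        "b_max": {f"b{k + 1}": float(b[:, k].max()) for k in range(4)},
        "domain_counts": {d: domains.count(d) for d in DOMAINS if domains.count(d)},
        "scale_counts": {s: scales.count(s) for s in SOURCE_SCALES if scales.count(s)},
    }
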