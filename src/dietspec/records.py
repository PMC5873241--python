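"""Prey-record data model, CSV input/output, and inclusion/exclusion filtering.

The unit of observation is a single prey item excavated from one nest cell of a
provisioning predator (here, a spider-hunting mud-dauber wasp).  Each record
carries the forager's identity, the cell (one discrete foraging bout), the
prey's taxonomic and functional classification, and two linear size measures.

Filtering follows the field protocol: cells with too few intact prey are
discarded, at most a fixed number of cells per individual are retained (chosen
uniformly at random with a seeded generator), prey unidentifiable to genus are
dropped from genus-level tabulations, and size-damaged specimens are dropped
from size analyses.
"""

from __future__ import annotations

import csv
import json
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: CSV tokens treated as a missing value (case-insensitive).
MISSING_TOKENS = frozenset({"", "na", "nan", "none", "null"})

_TRUE_TOKENS = frozenset({"1", "true", "t", "yes", "y"})
_FALSE_TOKENS = frozenset({"0", "false", "f", "no", "n"}) | MISSING_TOKENS

#: Classification levels at which a diet matrix can be built.
LEVELS = ("family", "genus", "guild")

#: Continuous prey-size measures recorded per item.
MEASURES = ("body_length", "carapace_width")

_CANONICAL_COLUMNS = (
    "individual_id",
    "cell_id",
    "family",
    "genus",
    "guild",
    "body_length_mm",
    "carapace_width_mm",
    "genus_unidentifiable",
    "size_damaged",
)


@dataclass(frozen=True)
class PreyRecord:
    """One captured prey item with its classification, size, and provenance.

    ``family`` may be missing only when the specimen is flagged
    ``genus_unidentifiable`` (damage severe enough to defeat identification).
    Sizes, when present, are strictly positive millimetres.
    """

    individual_id: str
    cell_id: str
    family: str | None = None
    genus: str | None = None
    guild: str | None = None
    body_length_mm: float | None = None
    carapace_width_mm: float | None = None
    genus_unidentifiable: bool = False
    size_damaged: bool = False

    def __post_init__(self) -> None:
        for attr in ("body_length_mm", "carapace_width_mm"):
            value = getattr(self, attr)
            if value is not None and not value > 0:
                raise ValueError(
                    f"{attr} must be positive when present, got {value!r} "
                    f"(individual {self.individual_id}, cell {self.cell_id})"
                )
        if self.genus_unidentifiable and self.genus is not None:
            # the flag wins: an unidentifiable specimen has no genus
            object.__setattr__(self, "genus", None)
        if self.family is None and not self.genus_unidentifiable:
            raise ValueError(
                "family is missing but the record is not flagged "
                f"genus_unidentifiable (individual {self.individual_id}, "
                f"cell {self.cell_id})"
            )


@dataclass(frozen=True)
class CellSelection:
    """Cell-level inclusion rules: minimum intact prey per cell and the
    maximum number of cells retained per individual (chosen at random)."""

    max_cells_per_individual: int = 3
    min_items_per_cell: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_cells_per_individual < 1:
            raise ValueError("max_cells_per_individual must be >= 1")
        if self.min_items_per_cell < 1:
            raise ValueError("min_items_per_cell must be >= 1")


@dataclass(frozen=True)
class DietMatrix:
    """Individuals x resource-categories count matrix at one classification level.

    Rows are individuals (each with at least one usable item), columns are
    resource categories observed at least once; both are ordered by first
    appearance in the source records.
    """

    individual_ids: tuple[str, ...]
    resource_labels: tuple[str, ...]
    counts: np.ndarray
    level: str

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        n, k = counts.shape
        if n != len(self.individual_ids) or k != len(self.resource_labels):
            raise ValueError("counts shape does not match the label vectors")
        if len(set(self.resource_labels)) != k:
            raise ValueError("resource labels must be unique")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if n and (counts.sum(axis=1) < 1).any():
            raise ValueError("every individual must contribute at least one item")
        if k and (counts.sum(axis=0) == 0).any():
            raise ValueError("all-zero resource columns are not allowed")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_resources(self) -> int:
        return len(self.resource_labels)

    def row_totals(self) -> np.ndarray:
        """Number of items per individual (n_i)."""
        return self.counts.sum(axis=1)

    def proportions(self) -> np.ndarray:
        """Row-normalised diet proportions p_ij."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def binary(self) -> np.ndarray:
        """Presence/absence matrix (counts thresholded at >= 1)."""
        return (self.counts >= 1).astype(np.int64)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.individual_ids, name="individual_id"),
            columns=list(self.resource_labels),
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def subset(self, individual_ids: Sequence[str]) -> "DietMatrix":
        """Restrict to the given individuals, dropping resource columns that
        become empty."""
        keep = [self.individual_ids.index(i) for i in individual_ids]
        counts = self.counts[keep]
        nonzero = counts.sum(axis=0) > 0
        return DietMatrix(
            individual_ids=tuple(individual_ids),
            resource_labels=tuple(
                lab for lab, nz in zip(self.resource_labels, nonzero) if nz
            ),
            counts=counts[:, nonzero],
            level=self.level,
        )


def _parse_bool(token: str, column: str, row_number: int) -> bool:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ValueError(f"row {row_number}: cannot parse boolean {column}={token!r}")


def _parse_float(token: str, column: str, row_number: int) -> float | None:
    t = token.strip()
    if t.lower() in MISSING_TOKENS:
        return None
    try:
        return float(t)
    except ValueError as exc:
        raise ValueError(f"row {row_number}: cannot parse {column}={token!r}") from exc


def _parse_str(token: str) -> str | None:
    t = token.strip()
    return None if t.lower() in MISSING_TOKENS else t


def read_records(path, dialect: Mapping[str, str] | None = None) -> list[PreyRecord]:
    """Read prey records from a UTF-8 CSV with a header row.

    Parameters
    ----------
    path
        CSV file path.
    dialect
        Optional mapping from canonical field names (``individual_id``,
        ``cell_id``, ``family``, ``genus``, ``guild``, ``body_length_mm``,
        ``carapace_width_mm``, ``genus_unidentifiable``, ``size_damaged``)
        to the column names actually present in the file.  Unmapped optional
        columns may be absent; ``individual_id`` and ``cell_id`` are required.

    Raises
    ------
    ValueError
        On a malformed row (the error names the 1-based data row number) or a
        non-positive size.
    """
    mapping = {name: name for name in _CANONICAL_COLUMNS}
    if dialect:
        mapping.update(dialect)

    records: list[PreyRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for required in ("individual_id", "cell_id"):
            if mapping[required] not in header:
                raise ValueError(
                    f"required column {mapping[required]!r} missing from header"
                )
        present = {name: mapping[name] in header for name in _CANONICAL_COLUMNS}
        for row_number, row in enumerate(reader, start=1):
            def get(name: str) -> str:
                return row.get(mapping[name]) or "" if present[name] else ""

            try:
                record = PreyRecord(
                    individual_id=get("individual_id").strip(),
                    cell_id=get("cell_id").strip(),
                    family=_parse_str(get("family")),
                    genus=_parse_str(get("genus")),
                    guild=_parse_str(get("guild")),
                    body_length_mm=_parse_float(
                        get("body_length_mm"), "body_length_mm", row_number
                    ),
                    carapace_width_mm=_parse_float(
                        get("carapace_width_mm"), "carapace_width_mm", row_number
                    ),
                    genus_unidentifiable=_parse_bool(
                        get("genus_unidentifiable"), "genus_unidentifiable", row_number
                    ),
                    size_damaged=_parse_bool(
                        get("size_damaged"), "size_damaged", row_number
                    ),
                )
            except ValueError as exc:
                raise ValueError(f"row {row_number}: {exc}") from exc
            if not record.individual_id or not record.cell_id:
                raise ValueError(
                    f"row {row_number}: individual_id and cell_id are required"
                )
            records.append(record)
    return records


def write_records(records: Iterable[PreyRecord], path) -> None:
    """Write records as CSV in the canonical column order (round-trips with
    :func:`read_records`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CANONICAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.individual_id,
                    r.cell_id,
                    r.family or "",
                    r.genus or "",
                    r.guild or "",
                    "" if r.body_length_mm is None else repr(r.body_length_mm),
                    "" if r.carapace_width_mm is None else repr(r.carapace_width_mm),
                    str(r.genus_unidentifiable).lower(),
                    str(r.size_damaged).lower(),
                ]
            )


def filter_cells(
    records: Sequence[PreyRecord],
    selection: CellSelection,
    rng: np.random.Generator | None = None,
    with_provenance: bool = False,
):
    """Apply the cell inclusion rules and the random cell subsample.

    Cells with fewer than ``selection.min_items_per_cell`` records are removed;
    then, per individual, if more than ``selection.max_cells_per_individual``
    cells remain, exactly that many are chosen uniformly at random.  The draw
    is deterministic given ``selection.seed`` (or the supplied ``rng``, which
    should be the pipeline's single named generator).

    An individual may end with zero cells and is then absent downstream.
    The operation is idempotent: re-filtering its own output (same seed)
    changes nothing, because no cell then violates either rule.

    Returns the filtered records in their original order; with
    ``with_provenance=True`` also returns a JSON-serialisable dict recording
    which cells were dropped and why.
    """
    if rng is None:
        rng = np.random.default_rng(selection.seed)

    cell_counts: dict[tuple[str, str], int] = {}
    cell_order: dict[str, list[str]] = {}
    for r in records:
        key = (r.individual_id, r.cell_id)
        if key not in cell_counts:
            cell_order.setdefault(r.individual_id, []).append(r.cell_id)
        cell_counts[key] = cell_counts.get(key, 0) + 1

    dropped_small: dict[str, list[str]] = {}
    dropped_random: dict[str, list[str]] = {}
    kept: dict[str, list[str]] = {}
    for individual, cells in cell_order.items():
        qualifying = [
            c for c in cells
            if cell_counts[(individual, c)] >= selection.min_items_per_cell
        ]
        small = [c for c in cells if c not in qualifying]
        if small:
            dropped_small[individual] = small
        if len(qualifying) > selection.max_cells_per_individual:
            chosen_idx = rng.choice(
                len(qualifying),
                size=selection.max_cells_per_individual,
                replace=False,
            )
            chosen = {qualifying[i] for i in chosen_idx}
            dropped_random[individual] = [c for c in qualifying if c not in chosen]
            qualifying = [c for c in qualifying if c in chosen]
        kept[individual] = qualifying

    keep_set = {(ind, c) for ind, cells in kept.items() for c in cells}
    out = [r for r in records if (r.individual_id, r.cell_id) in keep_set]
    if not with_provenance:
        return out
    provenance = {
        "selection": {
            "max_cells_per_individual": selection.max_cells_per_individual,
            "min_items_per_cell": selection.min_items_per_cell,
            "seed": selection.seed,
        },
        "cells_kept": {k: v for k, v in kept.items() if v},
        "cells_dropped_below_min_items": dropped_small,
        "cells_dropped_by_random_subsample": dropped_random,
    }
    return out, provenance


def write_provenance(provenance: Mapping, path) -> None:
    """Write a filtering-provenance sidecar as JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)


def build_diet_matrix(records: Sequence[PreyRecord], level: str) -> DietMatrix:
    """Tabulate records into an individuals x resources count matrix.

    At ``level='genus'`` records flagged ``genus_unidentifiable`` are excluded;
    at ``level='guild'`` records with a missing guild are dropped with a logged
    warning; at ``level='family'`` every record counts (family is always
    present unless genus-unidentifiable, in which case family may be missing
    and the record is skipped).  Rows and columns are ordered by first
    appearance among the counted records.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")

    usable: list[tuple[str, str]] = []
    n_dropped = 0
    for r in records:
        if level == "genus" and (r.genus_unidentifiable or r.genus is None):
            n_dropped += 1
            continue
        label = getattr(r, level)
        if label is None:
            n_dropped += 1
            continue
        usable.append((r.individual_id, label))
    if n_dropped:
        logger.warning(
            "build_diet_matrix(level=%s): dropped %d record(s) with missing or "
            "unidentifiable %s labels", level, n_dropped, level,
        )
    if not usable:
        raise ValueError(f"no usable records at level {level!r}")

    individuals: list[str] = []
    resources: list[str] = []
    for ind, lab in usable:
        if ind not in individuals:
            individuals.append(ind)
        if lab not in resources:
            resources.append(lab)
    counts = np.zeros((len(individuals), len(resources)), dtype=np.int64)
    ind_index = {x: i for i, x in enumerate(individuals)}
    res_index = {x: j for j, x in enumerate(resources)}
    for ind, lab in usable:
        counts[ind_index[ind], res_index[lab]] += 1
    return DietMatrix(
        individual_ids=tuple(individuals),
        resource_labels=tuple(resources),
        counts=counts,
        level=level,
    )


def extract_sizes(
    records: Sequence[PreyRecord], measure: str
) -> dict[str, list[float]]:
    """Group usable size measurements by individual.

    Size-damaged specimens and missing measurements are excluded.  An
    individual left with no usable sizes is dropped with a logged warning.
    ``measure`` is ``'body_length'`` or ``'carapace_width'``.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")
    attr = f"{measure}_mm"
    out: dict[str, list[float]] = {}
    seen: list[str] = []
    for r in records:
        if r.individual_id not in seen:
            seen.append(r.individual_id)
        if r.size_damaged:
            continue
        value = getattr(r, attr)
        if value is None:
            continue
        out.setdefault(r.individual_id, []).append(value)
    for ind in seen:
        if ind not in out:
            logger.warning(
                "extract_sizes(%s): individual %s has no usable sizes and is "
                "dropped", measure, ind,
            )
    # preserve first-appearance order
    return {ind: out[ind] for ind in seen if ind in out}
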