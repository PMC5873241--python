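"""Orchestration of the full specialization analysis on a record table.

Three designs mirror the field protocol:

``run_single_cell_analysis``
    One randomly selected qualifying cell per individual; for each prey
    classification level, the PS_i/IS test, the C_ws modularity test, and the
    NODF nestedness test; for each size measure, the WIC/TNW permutation test.

``run_temporal_analysis``
    Restricted to individuals with (at least) the full complement of
    qualifying cells (default 3); per-individual PS_i computed from one
    random cell and from all cells pooled, compared with a paired t-test per
    level.  Nest cells cannot be ordered in time, so cells are treated as
    unordered foraging bouts and pooled, never sequenced.  The reported mean
    difference is mean(single-cell PS_i) - mean(pooled PS_i): under
    temporally consistent diets it is near zero or positive; drifting diets
    push it negative (a single bout looks more specialized than the pooled
    record).

``run_subset_size_analysis``
    Restricted to individuals whose entire usable diet is one named resource
    (e.g. a single dominant orb-weaver genus): the WIC/TNW test per measure
    plus a one-way ANOVA of sizes among individuals, separating size
    specialization from taxon specialization.

All randomness (cell selection, null models) flows from one named generator
seeded with ``AnalysisConfig.seed``; reports are plain DataFrames/dicts and
serialise to CSV + JSON with a filtering-provenance sidecar, byte-identical
across re-runs with the same config and seed.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Sequence
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classical import one_way_anova, paired_t
from .diet import psi, psi_null_test
from .network import cws, nodf_null_test, overlap_network
from .nichewidth import wic_tnw_null_test
from .records import (
    CellSelection,
    PreyRecord,
    build_diet_matrix,
    extract_sizes,
    filter_cells,
    read_records,
)

logger = logging.getLogger(__name__)

_MAX_CHILD_SEED = 2**31 - 1


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the pipeline needs besides the records themselves."""

    levels: tuple[str, ...] = ("family", "genus", "guild")
    size_measures: tuple[str, ...] = ("body_length", "carapace_width")
    replicates: int = 999
    seed: int = 0
    min_items_per_cell: int = 5
    max_cells_per_individual: int = 3
    subset_resource: str | None = None
    subset_level: str = "genus"
    q_weighting: str = "equal"
    log_sizes: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.levels and not self.size_measures:
            raise ValueError("select at least one level or size measure")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        for key in ("levels", "size_measures"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class AnalysisReport:
    """Tables plus provenance from one pipeline run."""

    tables: dict[str, pd.DataFrame]
    provenance: dict
    results: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "provenance.json", "w", encoding="utf-8") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, _MAX_CHILD_SEED))


def _filtered(records, config: AnalysisConfig, max_cells: int, rng):
    selection = CellSelection(
        max_cells_per_individual=max_cells,
        min_items_per_cell=config.min_items_per_cell,
        seed=config.seed,
    )
    kept, provenance = filter_cells(
        records, selection, rng=rng, with_provenance=True
    )
    for ind, cells in provenance["cells_dropped_by_random_subsample"].items():
        logger.info("individual %s: cells %s dropped by random subsample",
                    ind, cells)
    return kept, provenance


def run_single_cell_analysis(
    records: Sequence[PreyRecord], config: AnalysisConfig
) -> AnalysisReport:
    """One random qualifying cell per individual; all index families."""
    rng = np.random.default_rng(config.seed)
    kept, provenance = _filtered(records, config, max_cells=1, rng=rng)
    if len({r.individual_id for r in kept}) < 2:
        raise ValueError("fewer than 2 individuals remain after cell filtering")

    psi_rows, cws_rows, nodf_rows, size_rows = [], [], [], []
    results: dict = {}
    for level in config.levels:
        diet = build_diet_matrix(kept, level)
        ps = psi_null_test(
            diet, config.replicates, seed=_child_seed(rng),
            q_weighting=config.q_weighting,
        )
        lo, hi = ps.psi_range
        psi_rows.append(
            {"level": level, "psi_min": lo, "psi_max": hi,
             "IS": ps.is_value, "p": ps.p_value}
        )
        results[f"psi_{level}"] = ps
        if diet.n_individuals >= 3:
            cw = cws(
                overlap_network(diet), diet, config.replicates,
                seed=_child_seed(rng), q_weighting=config.q_weighting,
            )
            cws_rows.append(
                {"level": level, "cws": cw.cws, "p": cw.p_value}
            )
            results[f"cws_{level}"] = cw
        nd = nodf_null_test(diet, config.replicates, seed=_child_seed(rng))
        nodf_rows.append(
            {"level": level, "nodf": nd.nodf, "nodf_null": nd.null_mean,
             "p": nd.p_value}
        )
        results[f"nodf_{level}"] = nd

    for measure in config.size_measures:
        sizes = extract_sizes(kept, measure)
        if len(sizes) < 2:
            logger.warning("measure %s: fewer than 2 individuals with usable "
                           "sizes; skipped", measure)
            continue
        nw = wic_tnw_null_test(
            sizes, config.replicates, seed=_child_seed(rng),
            log_transform=config.log_sizes,
        )
        size_rows.append(
            {"measure": measure, "wic": nw.wic, "bic": nw.bic, "tnw": nw.tnw,
             "wic_tnw": nw.ratio, "p": nw.p_value}
        )
        results[f"wic_tnw_{measure}"] = nw

    tables = {
        "individual_specialization": pd.DataFrame(
            psi_rows, columns=["level", "psi_min", "psi_max", "IS", "p"]
        ),
        "clustering": pd.DataFrame(cws_rows, columns=["level", "cws", "p"]),
        "nestedness": pd.DataFrame(
            nodf_rows, columns=["level", "nodf", "nodf_null", "p"]
        ),
        "niche_width": pd.DataFrame(
            size_rows,
            columns=["measure", "wic", "bic", "tnw", "wic_tnw", "p"],
        ),
    }
    return AnalysisReport(tables=tables, provenance=provenance, results=results)


def run_temporal_analysis(
    records: Sequence[PreyRecord], config: AnalysisConfig
) -> AnalysisReport:
    """Single-bout vs pooled multi-bout PS_i, paired t-test per level."""
    rng = np.random.default_rng(config.seed)
    kept, provenance = _filtered(
        records, config, max_cells=config.max_cells_per_individual, rng=rng
    )

    # individuals holding the full complement of qualifying cells
    cells_of: dict[str, list[str]] = {}
    for r in kept:
        cells = cells_of.setdefault(r.individual_id, [])
        if r.cell_id not in cells:
            cells.append(r.cell_id)
    eligible = [
        ind for ind, cells in cells_of.items()
        if len(cells) >= config.max_cells_per_individual
    ]
    if len(eligible) < 2:
        raise ValueError(
            f"temporal analysis needs >= 2 individuals with "
            f"{config.max_cells_per_individual} qualifying cells; found "
            f"{len(eligible)}"
        )
    single_cell_of = {
        ind: cells_of[ind][int(rng.integers(len(cells_of[ind])))]
        for ind in eligible
    }
    provenance["temporal_eligible_individuals"] = eligible
    provenance["temporal_single_cell"] = single_cell_of

    pooled_records = [r for r in kept if r.individual_id in eligible]
    single_records = [
        r for r in pooled_records
        if r.cell_id == single_cell_of[r.individual_id]
    ]

    rows = []
    results: dict = {}
    for level in config.levels:
        single = psi(build_diet_matrix(single_records, level),
                     q_weighting=config.q_weighting)
        pooled = psi(build_diet_matrix(pooled_records, level),
                     q_weighting=config.q_weighting)
        common = [i for i in eligible if i in single.psi and i in pooled.psi]
        x = [single.psi[i] for i in common]
        y = [pooled.psi[i] for i in common]
        test = paired_t(x, y)
        rows.append(
            {
                "level": level,
                "n": len(common),
                "mean_psi_single": float(np.mean(x)),
                "mean_psi_pooled": float(np.mean(y)),
                "mean_difference": float(np.mean(x) - np.mean(y)),
                "t": test.statistic,
                "df": test.df1,
                "p": test.p_value,
            }
        )
        results[f"temporal_{level}"] = test

    tables = {
        "temporal_consistency": pd.DataFrame(
            rows,
            columns=["level", "n", "mean_psi_single", "mean_psi_pooled",
                     "mean_difference", "t", "df", "p"],
        )
    }
    return AnalysisReport(tables=tables, provenance=provenance, results=results)


def run_subset_size_analysis(
    records: Sequence[PreyRecord], config: AnalysisConfig
) -> AnalysisReport:
    """Size specialization among individuals foraging exclusively on one
    resource (``config.subset_resource`` at ``config.subset_level``)."""
    if config.subset_resource is None:
        raise ValueError("subset_resource must name a resource")
    rng = np.random.default_rng(config.seed)
    kept, provenance = _filtered(
        records, config, max_cells=config.max_cells_per_individual, rng=rng
    )
    diet = build_diet_matrix(kept, config.subset_level)
    if config.subset_resource not in diet.resource_labels:
        raise ValueError(
            f"resource {config.subset_resource!r} not present at level "
            f"{config.subset_level!r}"
        )
    j = diet.resource_labels.index(config.subset_resource)
    exclusive = [
        ind for i, ind in enumerate(diet.individual_ids)
        if diet.counts[i, j] == diet.counts[i].sum()
    ]
    if len(exclusive) < 2:
        raise ValueError(
            f"only {len(exclusive)} individual(s) forage exclusively on "
            f"{config.subset_resource!r}; need >= 2"
        )
    provenance["subset_resource"] = config.subset_resource
    provenance["subset_individuals"] = exclusive
    subset_records = [r for r in kept if r.individual_id in exclusive]

    rows = []
    results: dict = {}
    for measure in config.size_measures:
        sizes = extract_sizes(subset_records, measure)
        sizes = {ind: v for ind, v in sizes.items() if ind in exclusive}
        if len(sizes) < 2:
            logger.warning("subset measure %s: fewer than 2 individuals with "
                           "usable sizes; skipped", measure)
            continue
        nw = wic_tnw_null_test(
            sizes, config.replicates, seed=_child_seed(rng),
            log_transform=config.log_sizes,
        )
        try:
            anova = one_way_anova(list(sizes.values()))
            f_stat, f_df1, f_df2, f_p = (
                anova.statistic, anova.df1, anova.df2, anova.p_value
            )
        except ValueError:
            f_stat = f_df1 = f_df2 = f_p = float("nan")
        rows.append(
            {
                "measure": measure,
                "n_individuals": len(sizes),
                "wic_tnw": nw.ratio,
                "p_wic_tnw": nw.p_value,
                "anova_F": f_stat,
                "anova_df1": f_df1,
                "anova_df2": f_df2,
                "anova_p": f_p,
            }
        )
        results[f"subset_wic_tnw_{measure}"] = nw

    tables = {
        "subset_size_specialization": pd.DataFrame(
            rows,
            columns=["measure", "n_individuals", "wic_tnw", "p_wic_tnw",
                     "anova_F", "anova_df1", "anova_df2", "anova_p"],
        )
    }
    return AnalysisReport(tables=tables, provenance=provenance, results=results)


def load_records(path, dialect=None) -> list[PreyRecord]:
    """Convenience wrapper around :func:`dietspec.records.read_records`."""
    return read_records(path, dialect)
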