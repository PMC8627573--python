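"""Study orchestration: environmental slicing and regression batteries.

Depth and temperature covary in most of the ocean, so the two predictors
are decorrelated by slicing: regressions against depth use only specimens
collected at <=7.5 degC (where temperature is nearly constant), and
regressions against temperature use only specimens from the upper 200 m
(where the pressure range is modest).  Both thresholds are inclusive.
Specimens in neither slice are excluded from environmental regressions but
retained for summary statistics and intercorrelations.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo import Phylogeny, RegressionResult, attach_individuals, fit_pgls
from .stats import holm_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "SpecimenRecord",
    "AnalysisConfig",
    "slice_for_depth",
    "slice_for_temperature",
    "run_battery",
    "per_species_ols",
    "intercorrelate",
    "write_report",
]

MAJOR_FAMES = ("C14:0", "C16:0", "C18:0", "C18:1", "C20:5", "C22:6")
SUMMARY_RESPONSES = ("dbi", "chain_length", "sfa", "mufa", "pufa")
DEFAULT_PAIRS = (
    ("C20:5", "C22:6"),
    ("C18:1", "C18:0"),
    ("C18:1", "C16:0"),
    ("C18:1", "C14:0"),
)


@dataclass(frozen=True)
class SpecimenRecord:
    """Collection metadata for one specimen."""

    sample_id: str
    taxon: str
    depth_m: float
    temp_C: float
    locale: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.depth_m) or self.depth_m < 0:
            raise ValueError(f"invalid depth {self.depth_m} for {self.sample_id}")
        if not math.isfinite(self.temp_C) or not (-2.0 <= self.temp_C <= 35.0):
            raise ValueError(f"invalid temperature {self.temp_C} for {self.sample_id}")


@dataclass
class AnalysisConfig:
    """Thresholds and families for the full regression battery."""

    depth_slice_max_temp: float = 7.5   # degC; depth regressions use T <= this
    temp_slice_max_depth: float = 200.0  # m; temperature regressions use z <= this
    inclusive_bounds: bool = True
    per_species_min_n: int = 6
    alpha: float = 0.05
    epsilon_frac: float = 1e-3
    major_fames: tuple[str, ...] = MAJOR_FAMES
    summary_responses: tuple[str, ...] = SUMMARY_RESPONSES
    ocfa_responses: tuple[str, ...] = ("C17:0", "C17:1")
    intercorrelation_pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS

    def __post_init__(self) -> None:
        if self.depth_slice_max_temp <= -2 or self.temp_slice_max_depth <= 0:
            raise ValueError("slice thresholds must be physically positive")


def _records_frame(records: Iterable[SpecimenRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        raise ValueError("no specimen records")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    return df.set_index("sample_id")


def slice_for_depth(
    records: Sequence[SpecimenRecord], config: AnalysisConfig | None = None
) -> list[SpecimenRecord]:
    """Specimens cold enough for depth regressions (T <= 7.5 degC)."""
    config = config or AnalysisConfig()
    t = config.depth_slice_max_temp
    if config.inclusive_bounds:
        out = [r for r in records if r.temp_C <= t]
    else:
        out = [r for r in records if r.temp_C < t]
    if not out:
        logger.warning("depth slice is empty at threshold %s degC", t)
    return out


def slice_for_temperature(
    records: Sequence[SpecimenRecord], config: AnalysisConfig | None = None
) -> list[SpecimenRecord]:
    """Specimens shallow enough for temperature regressions (z <= 200 m)."""
    config = config or AnalysisConfig()
    z = config.temp_slice_max_depth
    if config.inclusive_bounds:
        out = [r for r in records if r.depth_m <= z]
    else:
        out = [r for r in records if r.depth_m < z]
    if not out:
        logger.warning("temperature slice is empty at threshold %s m", z)
    return out


def _slice_distances(
    tree: Phylogeny,
    mapping: Mapping[str, str],
    sample_ids: Sequence[str],
    epsilon_frac: float,
) -> tuple[list[str], np.ndarray]:
    """Individual-level patristic distances for one slice's samples."""
    sub = {s: mapping[s] for s in sample_ids}
    norm = tree.normalized()
    expanded = attach_individuals(norm, sub, epsilon_frac * norm.height)
    return expanded.distance_matrix()


def _results_frame(results: Sequence[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def run_battery(
    metrics: pd.DataFrame,
    compositions: pd.DataFrame,
    records: Sequence[SpecimenRecord],
    tree: Phylogeny,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """The full PGLS battery with Holm correction per (predictor x panel).

    Panels: lipidome summaries (DBI, chain length, SFA/MUFA/PUFA) and the
    six major FAMEs against both depth and temperature; the C17 odd-chain
    pair against temperature; total fatty alcohols against both.  Each
    (predictor, panel) grouping is one Holm family.
    """
    config = config or AnalysisConfig()
    rec_df = _records_frame(records)
    mapping = rec_df["taxon"].to_dict()
    data = metrics.join(compositions, how="inner").join(rec_df, how="inner")
    if len(data) < len(metrics):
        logger.warning("dropped %d samples during join", len(metrics) - len(data))

    slices = {
        "depth": [r.sample_id for r in slice_for_depth(records, config) if r.sample_id in data.index],
        "temperature": [r.sample_id for r in slice_for_temperature(records, config) if r.sample_id in data.index],
    }
    predictors = {"depth": "depth_m", "temperature": "temp_C"}
    dist_cache: dict[str, tuple[list[str], np.ndarray]] = {}

    panels = [
        ("summary", list(config.summary_responses), ("depth", "temperature")),
        ("major_fames", [c for c in config.major_fames if c in data.columns], ("depth", "temperature")),
        ("ocfa", [c for c in config.ocfa_responses if c in data.columns], ("temperature",)),
        ("alcohol", ["alcohol"], ("depth", "temperature")),
    ]

    results: list[RegressionResult] = []
    panel_col: list[str] = []
    for panel_name, responses, slice_names in panels:
        missing = [r for r in responses if r not in data.columns]
        if missing:
            raise ValueError(f"missing response columns for panel {panel_name}: {missing}")
        for slice_name in slice_names:
            ids = slices[slice_name]
            if len(ids) < 3:
                raise ValueError(
                    f"{slice_name} slice has {len(ids)} usable samples; cannot regress"
                )
            if slice_name not in dist_cache:
                dist_cache[slice_name] = _slice_distances(
                    tree, mapping, ids, config.epsilon_frac
                )
            tip_order, D = dist_cache[slice_name]
            sub = data.loc[ids]
            family: list[RegressionResult] = []
            for resp in responses:
                family.append(
                    fit_pgls(
                        sub,
                        resp,
                        predictors[slice_name],
                        distances=D,
                        tip_order=tip_order,
                        slice_name=slice_name,
                    )
                )
            adj = holm_adjust([r.p for r in family])
            for r, ph in zip(family, adj):
                r.p_holm = float(ph)
            results.extend(family)
            panel_col.extend([panel_name] * len(family))

    out = _results_frame(results)
    out.insert(0, "panel", panel_col)
    out["significant"] = out["p_holm"] < config.alpha
    return out


def per_species_ols(
    metrics: pd.DataFrame,
    records: Sequence[SpecimenRecord],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Ordinary regressions per species, Holm-corrected within each species.

    For every taxon with at least ``per_species_min_n`` specimens inside a
    slice, each summary response is regressed on that slice's predictor by
    OLS; all of a species' rows form one Holm family.  Species below the
    threshold, and fits with a constant predictor, are skipped with a log
    entry.
    """
    config = config or AnalysisConfig()
    rec_df = _records_frame(records)
    data = metrics.join(rec_df, how="inner")

    slice_ids = {
        "depth": {r.sample_id for r in slice_for_depth(records, config)},
        "temperature": {r.sample_id for r in slice_for_temperature(records, config)},
    }
    predictors = {"depth": "depth_m", "temperature": "temp_C"}

    rows: list[dict] = []
    for taxon, group in data.groupby("taxon", sort=True):
        species_results: list[RegressionResult] = []
        for slice_name, pred in predictors.items():
            sub = group.loc[group.index.intersection(slice_ids[slice_name])]
            if len(sub) < config.per_species_min_n:
                logger.info(
                    "taxon %s: n=%d in %s slice (< %d); skipped",
                    taxon, len(sub), slice_name, config.per_species_min_n,
                )
                continue
            n = len(sub)
            for resp in config.summary_responses:
                if float(np.ptp(sub[pred].to_numpy())) == 0.0:
                    logger.warning(
                        "taxon %s: constant predictor %s; fit skipped", taxon, pred
                    )
                    continue
                species_results.append(
                    fit_pgls(
                        sub,
                        resp,
                        pred,
                        distances=np.zeros((n, n)),
                        tip_order=list(sub.index),
                        alpha=math.inf,
                        slice_name=slice_name,
                    )
                )
        if not species_results:
            continue
        adj = holm_adjust([r.p for r in species_results])
        for r, ph in zip(species_results, adj):
            r.p_holm = float(ph)
            row = dict(r.__dict__)
            row["taxon"] = taxon
            row["significant"] = r.p_holm < config.alpha
            rows.append(row)
    return pd.DataFrame(rows)


def intercorrelate(
    compositions: pd.DataFrame,
    records: Sequence[SpecimenRecord],
    tree: Phylogeny,
    pairs: Sequence[tuple[str, str]] | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """PGLS of one compound's fraction on another over the full specimen set.

    Intercorrelations use every specimen (no environmental slice applies);
    one Holm family spans all requested pairs.
    """
    config = config or AnalysisConfig()
    pairs = tuple(pairs) if pairs is not None else config.intercorrelation_pairs
    for a, b in pairs:
        if a == b:
            raise ValueError(f"degenerate intercorrelation pair ({a}, {a})")
        for lab in (a, b):
            if lab not in compositions.columns:
                raise ValueError(f"unknown compound {lab!r} in intercorrelation pair")
    rec_df = _records_frame(records)
    mapping = rec_df["taxon"].to_dict()
    data = compositions.join(rec_df, how="inner")
    tip_order, D = _slice_distances(tree, mapping, list(data.index), config.epsilon_frac)

    results = [
        fit_pgls(
            data, a, b,
            distances=D, tip_order=tip_order, slice_name="all",
        )
        for a, b in pairs
    ]
    adj = holm_adjust([r.p for r in results])
    for r, ph in zip(results, adj):
        r.p_holm = float(ph)
    out = _results_frame(results)
    out["significant"] = out["p_holm"] < config.alpha
    return out


def write_report(
    results: pd.DataFrame,
    path,
    *,
    seed: int | None = None,
    config: AnalysisConfig | None = None,
    title: str = "regressions",
) -> None:
    """Write a regression report as TSV with a reproducibility header."""
    from . import __version__

    if results.empty:
        raise ValueError("empty result set; nothing to report")
    cfg_hash = "-"
    if config is not None:
        blob = json.dumps(config.__dict__, sort_keys=True, default=str).encode()
        cfg_hash = hashlib.sha256(blob).hexdigest()[:12]
    header = (
        f"# {title}\n"
        f"# ctenofa version: {__version__}\n"
        f"# seed: {seed if seed is not None else '-'}\n"
        f"# config sha256/12: {cfg_hash}\n"
    )
    body = results.to_csv(sep="\t", index=False, float_format="%.10g", lineterminator="\n")
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(body)
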