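"""Descriptive statistics on a detection matrix.

Richness by grouping factor, shared/exclusive species overlaps, per-species
detection frequencies and rarity classes, positives-per-event distributions,
and event-level community distance matrices (Jaccard on incidence,
Bray-Curtis on positive-replicate counts).

All statistics are exact set/rational arithmetic on the incidence matrix; no
estimation is involved. Downstream hypothesis tests (rank tests, PERMANOVA,
ordination) are consumers of the tables and matrices exported here and are
deliberately not implemented.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_model import DetectionMatrix

FACTORS = ("location", "substrate", "season")


def round_half_away(x: float) -> int:
    """Nearest-integer rounding, ties away from zero (47.5 -> 48, not 47)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _level_species(matrix: DetectionMatrix, factor: str) -> dict[str, set[str]]:
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; valid: {FACTORS}")
    out: dict[str, set[str]] = {}
    for level, sub in matrix.events.groupby(factor):
        out[str(level)] = matrix.species_set(sub.index)
    return out


def richness(
    matrix: DetectionMatrix, group_by: Sequence[str] | str | None = None
) -> pd.Series:
    """Number of distinct species detected, overall or per group.

    ``group_by`` may be None (single overall count), ``"event"`` (per-event
    richness), or one or more of location/substrate/season. A species counts
    toward a group if it is incident in at least one event of that group.
    """
    if group_by is None:
        return pd.Series({"overall": len(matrix.species_set())})
    if isinstance(group_by, str):
        group_by = [group_by]
    if list(group_by) == ["event"]:
        return matrix.incidence.sum(axis=0)
    bad = [f for f in group_by if f not in FACTORS]
    if bad:
        raise ValueError(f"unknown factor(s) {bad}; valid: {FACTORS} or 'event'")
    out = {}
    for levels, sub in matrix.events.groupby(list(group_by)):
        key = levels if len(group_by) > 1 else levels[0] if isinstance(levels, tuple) else levels
        out[key] = len(matrix.species_set(sub.index))
    return pd.Series(out).sort_index()


@dataclass
class OverlapSummary:
    """Shared/exclusive species counts across the levels of a factor."""

    factor: str
    level_richness: dict[str, int]
    exclusive: dict[str, int]
    pairwise_shared: dict[tuple[str, str], int]
    shared_all: int
    union: int
    shared_all_pct: int  # percent of union, nearest integer, ties away from 0

    def as_dict(self) -> dict:
        return {
            "factor": self.factor,
            "level_richness": self.level_richness,
            "exclusive": self.exclusive,
            "pairwise_shared": {
                f"{a}&{b}": n for (a, b), n in self.pairwise_shared.items()
            },
            "shared_all": self.shared_all,
            "union": self.union,
            "shared_all_pct": self.shared_all_pct,
        }


def overlap_sets(
    sets_by_level: Mapping[str, set[str]], factor: str = "custom"
) -> OverlapSummary:
    """Set arithmetic over species sets, one per factor level."""
    levels = list(sets_by_level)
    if len(levels) < 2:
        raise ValueError("overlap needs at least two factor levels")
    union: set[str] = set().union(*sets_by_level.values())
    shared_all = set.intersection(*map(set, sets_by_level.values()))
    exclusive = {
        lv: len(
            sets_by_level[lv]
            - set().union(*(sets_by_level[o] for o in levels if o != lv))
        )
        for lv in levels
    }
    pairwise = {
        (a, b): len(sets_by_level[a] & sets_by_level[b])
        for a, b in combinations(levels, 2)
    }
    pct = round_half_away(100.0 * len(shared_all) / len(union)) if union else 0
    return OverlapSummary(
        factor=factor,
        level_richness={lv: len(sets_by_level[lv]) for lv in levels},
        exclusive=exclusive,
        pairwise_shared=pairwise,
        shared_all=len(shared_all),
        union=len(union),
        shared_all_pct=pct,
    )


def overlap(matrix: DetectionMatrix, factor: str) -> OverlapSummary:
    """Shared/exclusive species across the levels of an event factor."""
    sets_by_level = _level_species(matrix, factor)
    if len(sets_by_level) < 2:
        raise ValueError(f"factor {factor!r} has a single level in this matrix")
    return overlap_sets(sets_by_level, factor=factor)


def overlap_primers(
    matrices: Mapping[str, DetectionMatrix]
) -> OverlapSummary:
    """Shared/exclusive species across per-primer matrices of the same survey."""
    return overlap_sets(
        {scope: m.species_set() for scope, m in matrices.items()}, factor="primer"
    )


def detection_frequency(matrix: DetectionMatrix) -> pd.DataFrame:
    """Per-species detection frequency: proportion of sampling events in which
    the species was detected, overall and per substrate.

    The overall denominator is every event in the matrix regardless of
    substrate; per-substrate columns use that substrate's event count.
    Denominator columns are emitted alongside so frequencies remain exact
    rationals.
    """
    if matrix.n_events == 0:
        raise ValueError("matrix has no events")
    inc = matrix.incidence
    out = pd.DataFrame(index=inc.index)
    out["overall_events"] = inc.sum(axis=1)
    out["overall_denominator"] = matrix.n_events
    out["overall_frequency"] = out["overall_events"] / matrix.n_events
    for substrate, sub in matrix.events.groupby("substrate"):
        cols = list(sub.index)
        out[f"{substrate}_events"] = inc[cols].sum(axis=1)
        out[f"{substrate}_denominator"] = len(cols)
        out[f"{substrate}_frequency"] = out[f"{substrate}_events"] / len(cols)
    out.index.name = "species"
    return out


def classify_rarity(
    freqs: pd.DataFrame, threshold: float = 0.1
) -> pd.Series:
    """Label species "rare" (overall frequency strictly below threshold) or
    "abundant" (at or above); a frequency of exactly the threshold is abundant.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    rare = freqs["overall_frequency"] < threshold
    out = pd.Series(np.where(rare, "rare", "abundant"), index=freqs.index,
                    name="rarity")
    return out


@dataclass
class PositivesDistribution:
    """Histogram of positive-replicate counts over (species, event) detections."""

    histogram: dict[int, int]
    median: float
    mode: int
    n_detections: int


def positives_distribution(
    matrix: DetectionMatrix, by_substrate: bool = False
) -> PositivesDistribution | dict[str, PositivesDistribution]:
    """Distribution of positives-per-event over all detections (cells with at
    least one positive replicate). Mode ties resolve to the smallest count."""
    if by_substrate:
        return {
            str(substrate): positives_distribution(
                matrix.subset_events(list(sub.index))
            )
            for substrate, sub in matrix.events.groupby("substrate")
        }
    vals = matrix.positives.to_numpy().ravel()
    vals = vals[vals >= 1]
    if vals.size == 0:
        return PositivesDistribution(histogram={}, median=float("nan"),
                                     mode=0, n_detections=0)
    counts, freqs = np.unique(vals, return_counts=True)
    hist = dict(zip(counts.tolist(), freqs.tolist()))
    mode = int(counts[np.argmax(freqs)])  # np.unique sorts: ties -> smallest
    return PositivesDistribution(
        histogram=hist,
        median=float(np.median(vals)),
        mode=mode,
        n_detections=int(vals.size),
    )


def community_distance(
    matrix: DetectionMatrix, metric: str = "jaccard"
) -> pd.DataFrame:
    """Symmetric event-by-event distance matrix.

    Jaccard distance 1 - |A∩B|/|A∪B| on incidence; Bray-Curtis dissimilarity
    on positive-replicate counts. A pair of events with no species at all has
    distance 0 by convention (warned).
    """
    if matrix.n_events < 2:
        raise ValueError("need at least two events")
    if metric == "jaccard":
        data = matrix.incidence.to_numpy().T.astype(bool)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d = pdist(data, metric="jaccard")
    elif metric == "bray_curtis":
        data = matrix.positives.to_numpy().T.astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d = pdist(data, metric="braycurtis")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if np.isnan(d).any():
        warnings.warn(
            "event pair(s) with no detections: distance set to 0 by convention",
            stacklevel=2,
        )
        d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(
        squareform(d), index=matrix.event_ids, columns=matrix.event_ids
    )
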