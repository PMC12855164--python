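"""Sampling-design evaluation: accumulation curves and mixed-substrate designs.

Species accumulation curves answer "how much richness does the k-th sampling
event add?": event order is permuted, cumulative distinct-species counts are
taken along each permutation, and the mean with a confidence band is reported
per k. When the number of events is small (K <= 7) every ordering is
enumerated instead of sampled, making the mean exact.

The mixed-substrate comparison rebuilds the survey under three designs on the
same set of paired sampling days (days with full replicate sets in both
substrates): sediment-only, water-only, and a mixed design that pools k
randomly chosen replicates of each substrate into one event per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import (
    DetectionMatrix,
    SampleRecord,
    TaxonDetection,
    pool_by_event,
    synthesize_event_id,
)

EXHAUSTIVE_MAX_EVENTS = 7


@dataclass
class AccumulationCurve:
    """Mean cumulative richness and CI per number of sampling events."""

    k: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_permutations: int
    ci_level: float
    ci_method: str
    seed: int | None
    exhaustive: bool

    def as_frame(self, design: str = "") -> pd.DataFrame:
        df = pd.DataFrame(
            {"k": self.k, "mean": self.mean, "lower": self.lower,
             "upper": self.upper}
        )
        if design:
            df.insert(0, "design", design)
        return df


def accumulation_curve(
    matrix: DetectionMatrix,
    n_permutations: int = 1000,
    ci_level: float = 0.95,
    seed: int | None = None,
    ci_method: str = "percentile",
) -> AccumulationCurve:
    """Permutation species-accumulation curve over the matrix's events.

    For each permutation of event order the cumulative count of distinct
    species is recorded; the mean and a CI across permutations are reported at
    each k. With K <= 7 events all K! orderings are enumerated and the mean is
    exact. ``ci_method`` is "percentile" (empirical quantiles across
    orderings) or "sd" (mean +/- z * SD, the convention of classic ecology
    toolboxes).
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if ci_method not in ("percentile", "sd"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    inc = matrix.incidence.to_numpy()
    n_species, K = inc.shape
    if K == 0:
        raise ValueError("matrix has no events")

    exhaustive = K <= EXHAUSTIVE_MAX_EVENTS
    if exhaustive:
        orders = np.array(list(permutations(range(K))), dtype=int)
    else:
        rng = np.random.default_rng(seed)
        orders = np.array(
            [rng.permutation(K) for _ in range(n_permutations)], dtype=int
        )
    # cumulative richness along each ordering: species counted at first event
    # containing them
    curves = np.empty((orders.shape[0], K), dtype=int)
    for i, order in enumerate(orders):
        seen = np.zeros(n_species, dtype=bool)
        for j, e in enumerate(order):
            seen |= inc[:, e]
            curves[i, j] = seen.sum()
    mean = curves.mean(axis=0)
    alpha = 1 - ci_level
    if ci_method == "percentile":
        # widened minimally to contain the mean: on strongly skewed
        # permutation distributions an empirical quantile can cross it
        lower = np.minimum(np.quantile(curves, alpha / 2, axis=0), mean)
        upper = np.maximum(np.quantile(curves, 1 - alpha / 2, axis=0), mean)
    else:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        sd = curves.std(axis=0, ddof=1) if curves.shape[0] > 1 else np.zeros(K)
        lower = mean - z * sd
        upper = mean + z * sd
    return AccumulationCurve(
        k=np.arange(1, K + 1),
        mean=mean,
        lower=lower,
        upper=upper,
        n_permutations=orders.shape[0],
        ci_level=ci_level,
        ci_method=ci_method,
        seed=seed,
        exhaustive=exhaustive,
    )


def paired_days(
    samples: Sequence[SampleRecord],
    substrates: tuple[str, str] = ("water", "sediment"),
    min_replicates: int = 8,
) -> list[tuple[str, object]]:
    """(location, date) pairs with at least ``min_replicates`` replicates in
    both substrates on the same day at the same location."""
    counts: dict[tuple[str, object, str], int] = {}
    for s in samples:
        counts[(s.location, s.date, s.substrate)] = (
            counts.get((s.location, s.date, s.substrate), 0) + 1
        )
    days = sorted(
        {(loc, date) for loc, date, _ in counts}
    )
    return [
        (loc, date)
        for loc, date in days
        if all(counts.get((loc, date, sub), 0) >= min_replicates
               for sub in substrates)
    ]


def _restrict(
    detections: Sequence[TaxonDetection],
    samples: Sequence[SampleRecord],
    keep_ids: set[str],
) -> tuple[list[TaxonDetection], list[SampleRecord]]:
    kept_samples = [s for s in samples if s.sample_id in keep_ids]
    kept_detections = [d for d in detections if d.sample_id in keep_ids]
    return kept_detections, kept_samples


def build_mixed_design(
    detections: Sequence[TaxonDetection],
    samples: Sequence[SampleRecord],
    paired: Sequence[tuple[str, object]],
    k_sub: int = 4,
    n_draws: int = 1,
    seed: int | None = None,
    substrates: tuple[str, str] = ("water", "sediment"),
) -> tuple[list[DetectionMatrix], DetectionMatrix, DetectionMatrix]:
    """Build the mixed design and the matched single-substrate designs.

    For each paired day and draw, ``k_sub`` replicates are sampled without
    replacement from each substrate and pooled into one mixed event of
    2*k_sub replicates. Returns (list of mixed matrices, one per draw;
    substrate-one matrix; substrate-two matrix), the single-substrate
    matrices restricted to the paired days with their full replicate sets.
    """
    if k_sub < 0:
        raise ValueError("k_sub must be >= 0")
    paired_set = set(paired)
    by_day_sub: dict[tuple[str, object, str], list[SampleRecord]] = {}
    for s in samples:
        if (s.location, s.date) in paired_set and s.substrate in substrates:
            by_day_sub.setdefault((s.location, s.date, s.substrate), []).append(s)
    for loc, date in paired:
        for sub in substrates:
            avail = by_day_sub.get((loc, date, sub), [])
            if len(avail) < k_sub:
                raise ValueError(
                    f"day ({loc}, {date}) has {len(avail)} {sub} replicates, "
                    f"fewer than k_sub={k_sub}"
                )

    # single-substrate designs: full replicate sets on the paired days
    singles = []
    for sub in substrates:
        ids = {
            s.sample_id
            for (loc, date, s_sub), recs in by_day_sub.items()
            if s_sub == sub
            for s in recs
        }
        det, smp = _restrict(detections, samples, ids)
        singles.append(pool_by_event(det, smp, primer_scope="combined"))

    rng = np.random.default_rng(seed)
    mixed_matrices = []
    for _ in range(n_draws):
        chosen: list[SampleRecord] = []
        for loc, date in sorted(paired_set):
            for sub in substrates:
                recs = sorted(
                    by_day_sub[(loc, date, sub)], key=lambda s: s.sample_id
                )
                idx = rng.choice(len(recs), size=k_sub, replace=False)
                chosen.extend(recs[i] for i in sorted(idx))
        # relabel into one mixed event per day
        relabeled = []
        for i, s in enumerate(chosen):
            eid = synthesize_event_id(s.location, "mixed", s.date)
            relabeled.append(
                SampleRecord(
                    sample_id=s.sample_id,
                    event_id=eid,
                    location=s.location,
                    substrate="mixed",
                    season=s.season,
                    date=s.date,
                    replicate_index=i % (2 * k_sub) + 1 if k_sub else 1,
                    volume_ml=None,
                )
            )
        ids = {s.sample_id for s in relabeled}
        det = [d for d in detections if d.sample_id in ids]
        if k_sub == 0:
            # degenerate design: events exist but contain no replicates;
            # build an empty matrix over the paired days
            events = pd.DataFrame(
                {
                    "location": [loc for loc, _ in sorted(paired_set)],
                    "substrate": "mixed",
                    "season": "",
                    "date": [date for _, date in sorted(paired_set)],
                    "n_replicates": 0,
                },
                index=pd.Index(
                    [synthesize_event_id(loc, "mixed", date)
                     for loc, date in sorted(paired_set)],
                    name="event_id",
                ),
            )
            positives = pd.DataFrame(
                index=pd.Index([], name="species"), columns=events.index,
                dtype=int,
            )
            mixed_matrices.append(
                DetectionMatrix(positives, events, "combined")
            )
        else:
            mixed_matrices.append(
                pool_by_event(det, relabeled, primer_scope="combined")
            )
    return mixed_matrices, singles[0], singles[1]


@dataclass
class DesignSummary:
    mean_event_richness: float
    sd_event_richness: float
    overall_richness: float
    curve: AccumulationCurve
    n_events: int


@dataclass
class DesignComparison:
    """Per-design richness summaries built on the same paired sampling days."""

    designs: dict[str, DesignSummary]
    n_paired_days: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "design": name,
                    "mean_event_richness": s.mean_event_richness,
                    "sd_event_richness": s.sd_event_richness,
                    "overall_richness": s.overall_richness,
                    "n_events": s.n_events,
                }
                for name, s in self.designs.items()
            ]
        )


def _day_key(events: pd.DataFrame) -> set[tuple[str, object]]:
    return {(row["location"], row["date"]) for _, row in events.iterrows()}


def _summarize(
    matrices: Sequence[DetectionMatrix],
    n_permutations: int,
    seed: int | None,
) -> DesignSummary:
    """Summary for one design, averaged over draws when several matrices are
    given (the mixed design with n_draws > 1)."""
    means, sds, overalls, curves = [], [], [], []
    for i, m in enumerate(matrices):
        ev = m.incidence.sum(axis=0)
        means.append(float(ev.mean()))
        sds.append(float(ev.std(ddof=1)) if len(ev) > 1 else 0.0)
        overalls.append(float(len(m.species_set())))
        curves.append(
            accumulation_curve(
                m, n_permutations=n_permutations,
                seed=None if seed is None else seed + i,
            )
        )
    curve = curves[0]
    if len(curves) > 1:
        curve = AccumulationCurve(
            k=curves[0].k,
            mean=np.mean([c.mean for c in curves], axis=0),
            lower=np.mean([c.lower for c in curves], axis=0),
            upper=np.mean([c.upper for c in curves], axis=0),
            n_permutations=curves[0].n_permutations,
            ci_level=curves[0].ci_level,
            ci_method=curves[0].ci_method,
            seed=seed,
            exhaustive=curves[0].exhaustive,
        )
    return DesignSummary(
        mean_event_richness=float(np.mean(means)),
        sd_event_richness=float(np.mean(sds)),
        overall_richness=float(np.mean(overalls)),
        curve=curve,
        n_events=matrices[0].n_events,
    )


def compare_designs(
    mixed: DetectionMatrix | Sequence[DetectionMatrix],
    sediment_only: DetectionMatrix,
    water_only: DetectionMatrix,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> DesignComparison:
    """Compare mixed vs single-substrate designs built on identical paired days."""
    mixed_list = [mixed] if isinstance(mixed, DetectionMatrix) else list(mixed)
    days = _day_key(mixed_list[0].events)
    for m in (sediment_only, water_only, *mixed_list[1:]):
        if _day_key(m.events) != days:
            raise ValueError("designs built on mismatched day sets")
    return DesignComparison(
        designs={
            "mixed": _summarize(mixed_list, n_permutations, seed),
            "sediment_only": _summarize([sediment_only], n_permutations,
                                        None if seed is None else seed + 1000),
            "water_only": _summarize([water_only], n_permutations,
                                     None if seed is None else seed + 2000),
        },
        n_paired_days=len(days),
    )


def volume_richness_table(
    matrix: DetectionMatrix, samples: Sequence[SampleRecord]
) -> pd.DataFrame:
    """Per water event: total filtered volume and per-event richness, shaped
    for a downstream count regression. Events missing all volumes are dropped
    (count logged via the returned table's attrs)."""
    import logging

    logger = logging.getLogger(__name__)
    water_events = matrix.events[matrix.events["substrate"] == "water"]
    per_event_richness = matrix.incidence.sum(axis=0)
    vol_by_event: dict[str, float] = {}
    seen: dict[str, int] = {}
    for s in samples:
        if s.event_id in water_events.index and s.volume_ml is not None:
            vol_by_event[s.event_id] = vol_by_event.get(s.event_id, 0.0) + s.volume_ml
            seen[s.event_id] = seen.get(s.event_id, 0) + 1
    rows = []
    dropped = 0
    for eid in water_events.index:
        if eid not in vol_by_event:
            dropped += 1
            continue
        rows.append(
            {
                "event_id": eid,
                "volume_ml": vol_by_event[eid],
                "richness": int(per_event_richness[eid]),
            }
        )
    if dropped:
        logger.info("dropped %d water events with no volume data", dropped)
    df = pd.DataFrame(rows, columns=["event_id", "volume_ml", "richness"])
    df.attrs["n_dropped"] = dropped
    return df
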