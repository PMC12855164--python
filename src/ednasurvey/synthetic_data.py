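"""Synthetic surveys with known truth.

The generator emulates the detection structure of a multi-substrate eDNA
waterhole survey with a two-level Bernoulli hierarchy:

* event level — species ``s`` has detectable DNA at a sampling event with
  probability ``psi_s * m_{s, season}`` (availability times a seasonal
  multiplier);
* replicate level — given availability, each replicate sample detects the
  species under primer ``q`` with probability
  ``p_{s, substrate} * a_{s, q} * v(r)``, where ``p`` is the substrate
  capture probability, ``a`` the primer amplification efficiency and ``v(r)``
  an optional filtered-volume effect for water replicates.

This is the simplest generative structure consistent with every downstream
analysis (pooling, detection frequency, accumulation, design comparison); it
is a test harness, not a model of eDNA transport. Read counts are drawn as
shifted-geometric decoration: nothing downstream uses their magnitude.

All randomness flows through one numpy Generator whose draw order is fixed by
the survey layout and never by parameter values, so two runs with the same
seed but different probabilities share their underlying uniform variates —
raising a capture probability can then only add detections (monotone
coupling).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import (
    PRIMERS,
    SampleRecord,
    TaxonDetection,
)
from .taxon_filter import CurationRules, OccurrenceCatalog, ReferenceCatalog

SEASON_START = {"wet": _dt.date(2023, 3, 10), "dry": _dt.date(2023, 9, 9)}
DAY_INTERVAL = 6


@dataclass
class SpeciesParams:
    """Per-species detection parameters of the two-level model."""

    name: str
    availability: float  # psi: event-level presence of detectable DNA
    capture: dict[str, float]  # substrate -> per-replicate capture prob
    season_multiplier: dict[str, float]  # season -> multiplier on psi
    amplification: dict[str, float]  # primer -> amplification prob

    def validate(self) -> None:
        probs = [self.availability, *self.capture.values(),
                 *self.season_multiplier.values(), *self.amplification.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError(f"{self.name}: probability outside [0, 1]")


@dataclass
class EventSpec:
    location: str
    substrate: str
    season: str
    day_index: int  # sampling-day number within the season, 0-based


@dataclass
class SyntheticConfig:
    """Full parameterization of the survey simulator."""

    species: list[SpeciesParams]
    events: list[EventSpec]
    replicates: dict[str, int] = field(
        default_factory=lambda: {"water": 8, "sediment": 8, "soil": 6}
    )
    volume_mean: float = 400.0
    volume_sd: float = 100.0
    volume_slope: float = 0.0  # exponent of (volume/volume_mean) on capture
    seed: int = 0

    def validate(self) -> None:
        for sp in self.species:
            sp.validate()
        if len({sp.name for sp in self.species}) != len(self.species):
            raise ValueError("duplicate species names")
        for ev in self.events:
            if ev.substrate not in self.replicates:
                raise ValueError(f"no replicate count for {ev.substrate!r}")
            if self.replicates[ev.substrate] < 1:
                raise ValueError("replicate counts must be positive")
        if self.volume_mean <= 0 or self.volume_sd < 0:
            raise ValueError("invalid volume model")


@dataclass
class TruthRecord:
    """Ground truth of one simulated survey.

    ``availability[s, e]`` is the event-level presence draw;
    ``detected[s, i, q]`` the replicate-level outcome for sample i and primer
    q. ``sample_ids`` aligns axis 1 of ``detected``.
    """

    species: list[str]
    event_ids: list[str]
    sample_ids: list[str]
    availability: np.ndarray  # bool (S, E)
    detected: np.ndarray  # bool (S, N_samples, P)
    sample_event_index: np.ndarray  # int (N_samples,) into event_ids
    config: SyntheticConfig
    seed: int


def _event_date(ev: EventSpec) -> _dt.date:
    return SEASON_START[ev.season] + _dt.timedelta(days=DAY_INTERVAL * ev.day_index)


def generate_survey(
    config: SyntheticConfig,
) -> tuple[list[SampleRecord], list[TaxonDetection], TruthRecord]:
    """Simulate one survey: metadata, species-level assignments, and truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    S = len(config.species)
    psi = np.array([sp.availability for sp in config.species])
    names = [sp.name for sp in config.species]

    samples: list[SampleRecord] = []
    detections: list[TaxonDetection] = []
    event_ids: list[str] = []
    avail_cols: list[np.ndarray] = []
    det_blocks: list[np.ndarray] = []
    sample_event_index: list[int] = []
    all_sample_ids: list[str] = []

    for e_idx, ev in enumerate(config.events):
        R = config.replicates[ev.substrate]
        date = _event_date(ev)
        eid = f"{ev.location}|{ev.substrate}|{date.isoformat()}"
        event_ids.append(eid)

        m = np.array(
            [sp.season_multiplier.get(ev.season, 1.0) for sp in config.species]
        )
        p_sub = np.array(
            [sp.capture.get(ev.substrate, 0.0) for sp in config.species]
        )
        amp = np.array(
            [[sp.amplification.get(q, 0.0) for q in PRIMERS]
             for sp in config.species]
        )  # (S, P)

        # fixed draw order: availability, volumes, detection uniforms, reads
        u_avail = rng.random(S)
        volumes = rng.normal(config.volume_mean, config.volume_sd, size=R)
        volumes = np.clip(volumes, 0.1 * config.volume_mean, None)
        u_det = rng.random((S, R, len(PRIMERS)))
        reads = rng.geometric(0.01, size=(S, R, len(PRIMERS)))

        available = u_avail < psi * m
        if ev.substrate == "water" and config.volume_slope != 0.0:
            v = (volumes / config.volume_mean) ** config.volume_slope
        else:
            v = np.ones(R)
        p_eff = np.clip(
            p_sub[:, None, None] * v[None, :, None] * amp[:, None, :], 0.0, 1.0
        )
        detected = available[:, None, None] & (u_det < p_eff)

        avail_cols.append(available)
        det_blocks.append(detected)

        sids = []
        for r in range(R):
            sid = f"{ev.location}-{ev.substrate}-{ev.season}{ev.day_index}-r{r + 1}"
            sids.append(sid)
            all_sample_ids.append(sid)
            sample_event_index.append(e_idx)
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    event_id=eid,
                    location=ev.location,
                    substrate=ev.substrate,
                    season=ev.season,
                    date=date,
                    replicate_index=r + 1,
                    volume_ml=float(volumes[r]) if ev.substrate == "water" else None,
                )
            )
        for s, r, q_idx in np.argwhere(detected):
            detections.append(
                TaxonDetection(
                    sample_id=sids[r],
                    primer=PRIMERS[q_idx],
                    taxon_name=names[s],
                    rank="species",
                    read_count=int(reads[s, r, q_idx]),
                )
            )

    truth = TruthRecord(
        species=names,
        event_ids=event_ids,
        sample_ids=all_sample_ids,
        availability=np.stack(avail_cols, axis=1),
        detected=np.concatenate(det_blocks, axis=1),
        sample_event_index=np.array(sample_event_index),
        config=config,
        seed=config.seed,
    )
    return samples, detections, truth


def matrix_from_truth(truth: TruthRecord, primer_scope: str = "combined"):
    """Build the DetectionMatrix directly from truth arrays (vectorized).

    Equivalent to pooling the emitted assignment table with
    :func:`ednasurvey.io_model.pool_by_event`; the equivalence is exercised in
    the test suite, and this path is preferred for large simulated surveys.
    """
    from .io_model import DetectionMatrix

    cfg = truth.config
    if primer_scope == "combined":
        det = truth.detected.any(axis=2)  # (S, N_samples)
    else:
        det = truth.detected[:, :, PRIMERS.index(primer_scope)]
    S = len(truth.species)
    E = len(truth.event_ids)
    positives = np.zeros((S, E), dtype=int)
    for e in range(E):
        positives[:, e] = det[:, truth.sample_event_index == e].sum(axis=1)
    events_rows = []
    for ev in cfg.events:
        date = _event_date(ev)
        events_rows.append(
            {
                "event_id": f"{ev.location}|{ev.substrate}|{date.isoformat()}",
                "location": ev.location,
                "substrate": ev.substrate,
                "season": ev.season,
                "date": date,
                "n_replicates": cfg.replicates[ev.substrate],
            }
        )
    events = pd.DataFrame(events_rows).set_index("event_id")
    pos = pd.DataFrame(positives, index=truth.species, columns=truth.event_ids)
    pos.index.name = "species"
    return DetectionMatrix(pos, events, primer_scope)


# ---------------------------------------------------------------------------
# Presets


def grid_events(
    locations: Sequence[str],
    substrates: Sequence[str],
    seasons: Sequence[str],
    days: int,
) -> list[EventSpec]:
    """One event per (location, substrate, season, sampling day)."""
    return [
        EventSpec(location=loc, substrate=sub, season=sea, day_index=d)
        for loc in locations
        for sub in substrates
        for sea in seasons
        for d in range(days)
    ]


def savanna_preset(
    n_species: int = 95,
    seed: int = 0,
    days_per_season: int = 8,
    soil_days: int = 4,
    volume_slope: float = 0.0,
) -> SyntheticConfig:
    """Default survey: three waterholes sampled for water and sediment in wet
    and dry seasons, plus dry-season soil from three wildlife trails.

    Species detection parameters are drawn once (from ``seed``) with a
    long-tail profile: most species are rarely available and weakly captured,
    a few are ubiquitous — yielding detection frequencies spanning roughly
    0.01-0.9 and the patchy one-positive-replicate-per-event signature typical
    of waterhole surveys.
    """
    rng = np.random.default_rng(seed)
    species = []
    for i in range(n_species):
        amp = {}
        for q in PRIMERS:
            # most species amplify with one or both primers, some with neither
            amp[q] = float(rng.uniform(0.5, 1.0)) if rng.random() < 0.7 else float(
                rng.uniform(0.0, 0.1)
            )
        species.append(
            SpeciesParams(
                name=f"Sp{i:03d}",
                availability=float(rng.beta(1.3, 1.6)),
                capture={
                    "water": float(rng.beta(1.2, 6.0)),
                    "sediment": float(rng.beta(1.2, 6.0)),
                    "soil": float(rng.beta(1.0, 9.0)),
                },
                season_multiplier={
                    "wet": float(rng.uniform(0.6, 1.0)),
                    "dry": float(rng.uniform(0.4, 1.0)),
                },
                amplification=amp,
            )
        )
    events = grid_events(
        ["WaterholeA", "WaterholeB", "WaterholeC"],
        ["water", "sediment"],
        ["wet", "dry"],
        days_per_season,
    )
    events += grid_events(
        ["TrailA", "TrailB", "TrailC"], ["soil"], ["dry"], soil_days
    )
    return SyntheticConfig(
        species=species, events=events, volume_slope=volume_slope, seed=seed
    )


# ---------------------------------------------------------------------------
# Parameter recovery


def analytic_event_detection(
    sp: SpeciesParams, substrate: str, season: str, n_replicates: int
) -> float:
    """Closed-form event-level detection probability of the two-level model
    (volume effect at its neutral value v = 1):
    ``psi * m * (1 - prod_r (1 - per-replicate prob))`` where the
    per-replicate probability unions the primers."""
    p = sp.capture.get(substrate, 0.0)
    miss_rep = 1.0
    for q in PRIMERS:
        miss_rep *= 1.0 - p * sp.amplification.get(q, 0.0)
    per_rep = 1.0 - miss_rep
    return (
        sp.availability
        * sp.season_multiplier.get(season, 1.0)
        * (1.0 - (1.0 - per_rep) ** n_replicates)
    )


def recover_detection_params(matrix, truth: TruthRecord) -> pd.DataFrame:
    """Compare empirical event-level detection frequencies against the
    analytic expectation, per species and (substrate, season) stratum.

    Returns a table with empirical and analytic frequency, bias, the
    Monte-Carlo standard error ``sqrt(d(1-d)/n)``, and a ``usable`` flag
    (False when the stratum has a single event, where the SE denominator is
    meaningless).
    """
    cfg = truth.config
    inc = matrix.incidence
    by_sp = {sp.name: sp for sp in cfg.species}
    rows = []
    for (substrate, season), sub in matrix.events.groupby(["substrate", "season"]):
        eids = list(sub.index)
        n = len(eids)
        R = cfg.replicates[substrate]
        for name in matrix.species:
            if name not in by_sp:
                continue
            sp = by_sp[name]
            d = analytic_event_detection(sp, substrate, season, R)
            emp = float(inc.loc[name, eids].mean())
            se = float(np.sqrt(d * (1 - d) / n)) if n > 1 else float("nan")
            rows.append(
                {
                    "species": name,
                    "substrate": substrate,
                    "season": season,
                    "n_events": n,
                    "analytic": d,
                    "empirical": emp,
                    "bias": emp - d,
                    "mc_se": se,
                    "usable": n > 1,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Taxonomy-challenge generator


@dataclass
class ChallengeSpec:
    """Counts of curation scenarios to inject into an assignment table.

    Each scenario has a ground-truth decision known by construction:

    * documented_accept — documented species label, accepted;
    * unique_congener — non-documented label in a genus whose single
      documented species lacks a reference: reassigned under both ambiguity
      modes;
    * missing_reference_congener — non-documented label in a genus with
      several documented congeners of which exactly one lacks a reference:
      ambiguous (excluded) when all documented congeners count, reassigned
      when only unreferenced congeners count;
    * ambiguous_congeners — several documented congeners, all unreferenced:
      excluded under both modes;
    * no_congener — genus without documented species: excluded;
    * blocklisted / override — rule-table hits.
    """

    documented_accept: int = 0
    unique_congener: int = 0
    missing_reference_congener: int = 0
    ambiguous_congeners: int = 0
    no_congener: int = 0
    blocklisted: int = 0
    override: int = 0

    def total(self) -> int:
        return sum(asdict(self).values())


def challenge_catalogs(
    spec: ChallengeSpec, rules: CurationRules
) -> tuple[OccurrenceCatalog, ReferenceCatalog]:
    """Build synthetic occurrence/reference catalogs rich enough to realize
    every scenario in ``spec`` (plus the rule tables' species)."""
    documented: set[str] = set()
    reference: dict[str, bool] = {}
    for i in range(max(spec.documented_accept, 1)):
        sp = f"Docgenus{i:02d} verus"
        documented.add(sp)
        reference[sp] = True
    for i in range(max(spec.unique_congener, 1)):
        sp = f"Unigenus{i:02d} solus"
        documented.add(sp)
        reference[sp] = False  # the single documented congener lacks a reference
    for i in range(max(spec.missing_reference_congener, 1)):
        for j, has_ref in enumerate([True, True, False]):
            sp = f"Gapgenus{i:02d} sp{j}"
            documented.add(sp)
            reference[sp] = has_ref
    for i in range(max(spec.ambiguous_congeners, 1)):
        for j in range(3):
            sp = f"Ambigenus{i:02d} sp{j}"
            documented.add(sp)
            reference[sp] = False
    for target in rules.overrides.values():
        documented.add(target)
        reference.setdefault(target, False)
    return (
        OccurrenceCatalog(documented_species=documented),
        ReferenceCatalog.from_mapping(reference),
    )


def generate_challenge(
    spec: ChallengeSpec,
    occ: OccurrenceCatalog,
    ref: ReferenceCatalog,
    rules: CurationRules,
    seed: int = 0,
) -> tuple[list[TaxonDetection], pd.DataFrame]:
    """Emit an assignment table realizing each scenario the stated number of
    times, with a ground-truth decision table.

    The truth table records the expected action/reason under both ambiguity
    modes (columns ``action_documented`` / ``action_unreferenced`` etc.).
    Raises if the catalogs cannot realize a scenario.
    """
    rng = np.random.default_rng(seed)
    genera_by_kind: dict[str, list[str]] = {"unique": [], "gap": [],
                                            "ambiguous": [], "empty": []}
    for genus, sps in occ.genus_index.items():
        unreferenced = [s for s in sps if ref.lacks_reference(s)]
        if len(sps) == 1 and len(unreferenced) == 1:
            genera_by_kind["unique"].append(genus)
        elif len(sps) >= 2 and len(unreferenced) == 1:
            genera_by_kind["gap"].append(genus)
        elif len(sps) >= 2 and len(unreferenced) >= 2:
            genera_by_kind["ambiguous"].append(genus)
    plain_documented = sorted(
        occ.documented_species
        - rules.blocklist - rules.anthropogenic - set(rules.overrides)
        - set(rules.overrides.values())
    )

    rows: list[dict] = []

    def need(pool: list, n: int, scenario: str) -> list:
        if len(pool) < n:
            raise ValueError(
                f"catalogs cannot realize scenario {scenario!r}: "
                f"need {n}, found {len(pool)}"
            )
        return pool[:n]

    for sp_name in need(plain_documented, spec.documented_accept,
                        "documented_accept"):
        rows.append(dict(label=sp_name, rank="species",
                         scenario="documented_accept",
                         action_documented="accept", reason_documented="documented",
                         final_documented=sp_name,
                         action_unreferenced="accept",
                         reason_unreferenced="documented",
                         final_unreferenced=sp_name))
    for k, genus in enumerate(need(sorted(genera_by_kind["unique"]),
                                   spec.unique_congener, "unique_congener")):
        target = occ.congeners(genus)[0]
        rank = "genus" if k % 2 else "species"
        label = genus if rank == "genus" else f"{genus} alienus"
        rows.append(dict(label=label, rank=rank, scenario="unique_congener",
                         action_documented="reassign",
                         reason_documented="unique_congener",
                         final_documented=target,
                         action_unreferenced="reassign",
                         reason_unreferenced="unique_congener",
                         final_unreferenced=target))
    for genus in need(sorted(genera_by_kind["gap"]),
                      spec.missing_reference_congener,
                      "missing_reference_congener"):
        target = [s for s in occ.congeners(genus) if ref.lacks_reference(s)][0]
        rows.append(dict(label=f"{genus} alienus", rank="species",
                         scenario="missing_reference_congener",
                         action_documented="exclude",
                         reason_documented="ambiguous_congeners",
                         final_documented=None,
                         action_unreferenced="reassign",
                         reason_unreferenced="unique_congener",
                         final_unreferenced=target))
    for k, genus in enumerate(need(sorted(genera_by_kind["ambiguous"]),
                                   spec.ambiguous_congeners,
                                   "ambiguous_congeners")):
        rank = "genus" if k % 2 else "species"
        label = genus if rank == "genus" else f"{genus} alienus"
        rows.append(dict(label=label, rank=rank, scenario="ambiguous_congeners",
                         action_documented="exclude",
                         reason_documented="ambiguous_congeners",
                         final_documented=None,
                         action_unreferenced="exclude",
                         reason_unreferenced="ambiguous_congeners",
                         final_unreferenced=None))
    for i in range(spec.no_congener):
        rows.append(dict(label=f"Nullgenus{i:02d} ignotus", rank="species",
                         scenario="no_congener",
                         action_documented="exclude",
                         reason_documented="no_congener", final_documented=None,
                         action_unreferenced="exclude",
                         reason_unreferenced="no_congener",
                         final_unreferenced=None))
    for name in need(sorted(rules.blocklist | rules.anthropogenic),
                     spec.blocklisted, "blocklisted"):
        reason = "anthropogenic" if name in rules.anthropogenic else "blocklisted"
        rows.append(dict(label=name, rank="species", scenario="blocklisted",
                         action_documented="exclude", reason_documented=reason,
                         final_documented=None,
                         action_unreferenced="exclude",
                         reason_unreferenced=reason, final_unreferenced=None))
    for name in need(sorted(rules.overrides), spec.override, "override"):
        target = rules.overrides[name]
        rows.append(dict(label=name, rank="species", scenario="override",
                         action_documented="reassign",
                         reason_documented="override", final_documented=target,
                         action_unreferenced="reassign",
                         reason_unreferenced="override",
                         final_unreferenced=target))

    detections = []
    for i, row in enumerate(rows):
        for j in range(int(rng.integers(1, 4))):
            detections.append(
                TaxonDetection(
                    sample_id=f"chal-s{(i * 3 + j) % 24 + 1:02d}",
                    primer=PRIMERS[int(rng.integers(0, 2))],
                    taxon_name=row["label"],
                    rank=row["rank"],
                    read_count=int(rng.integers(1, 5000)),
                )
            )
    truth = pd.DataFrame(rows)
    return detections, truth
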