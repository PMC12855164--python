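"""Detection data model and tabular I/O.

An eDNA waterhole survey is organized around *sampling events*: all replicate
samples of one substrate (water, sediment, or soil) collected at one location
on one day. Replicates within an event are pooled for analysis, but the number
of positive replicates per species and event is retained, since replicate-level
patchiness is itself informative.

Canonical on-disk dialect is UTF-8 tab-separated tables with named headers;
comma-separated input is accepted via ``sep=","``.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBSTRATES = ("water", "sediment", "soil")
SEASONS = ("wet", "dry")
PRIMERS = ("12SV5", "MiMammal")
PRIMER_SCOPES = ("12SV5", "MiMammal", "combined")


class ValidationError(ValueError):
    """Raised when an input table violates the data model."""


@dataclass(frozen=True)
class SampleRecord:
    """One replicate sample (a bottle of water, a tube of sediment or soil)."""

    sample_id: str
    event_id: str
    location: str
    substrate: str
    season: str
    date: _dt.date
    replicate_index: int
    volume_ml: float | None = None

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATES and self.substrate != "mixed":
            raise ValidationError(f"unknown substrate {self.substrate!r}")
        if self.season not in SEASONS:
            raise ValidationError(f"unknown season {self.season!r}")
        if self.replicate_index < 1:
            raise ValidationError("replicate_index must be >= 1")
        if self.substrate == "soil" and self.volume_ml is not None:
            raise ValidationError(
                f"soil sample {self.sample_id!r} must not carry volume_ml"
            )
        if self.volume_ml is not None and self.volume_ml < 0:
            raise ValidationError("volume_ml must be nonnegative")


@dataclass(frozen=True)
class TaxonDetection:
    """One taxonomic assignment in one sample under one primer."""

    sample_id: str
    primer: str
    taxon_name: str
    rank: str
    read_count: int

    def __post_init__(self) -> None:
        if self.primer not in PRIMERS:
            raise ValidationError(f"unknown primer {self.primer!r}")
        if self.rank not in ("species", "genus"):
            raise ValidationError(f"unknown rank {self.rank!r}")
        if not self.taxon_name:
            raise ValidationError("taxon_name must be nonempty")
        if self.read_count < 1:
            raise ValidationError("retained detection needs read_count >= 1")


@dataclass(frozen=True)
class SamplingEvent:
    """All replicates of one substrate at one location on one day."""

    event_id: str
    location: str
    substrate: str
    season: str
    date: _dt.date
    n_replicates: int


def synthesize_event_id(location: str, substrate: str, date: _dt.date) -> str:
    return f"{location}|{substrate}|{date.isoformat()}"


class DetectionMatrix:
    """Species-by-event detection matrix with positive-replicate counts.

    Parameters
    ----------
    positives
        Integer DataFrame, species rows by event-id columns; cell value is the
        number of positive replicates for that species in that event.
    events
        DataFrame indexed by event_id with columns ``location``, ``substrate``,
        ``season``, ``date``, ``n_replicates``.
    primer_scope
        Which primer dataset the matrix represents: ``"12SV5"``,
        ``"MiMammal"``, or ``"combined"``.
    """

    def __init__(
        self, positives: pd.DataFrame, events: pd.DataFrame, primer_scope: str
    ) -> None:
        if primer_scope not in PRIMER_SCOPES:
            raise ValidationError(f"unknown primer_scope {primer_scope!r}")
        if positives.index.duplicated().any():
            raise ValidationError("duplicate species in matrix")
        if list(positives.columns) != list(events.index):
            raise ValidationError("positives columns must match event index")
        exceeds = positives.gt(events["n_replicates"], axis=1)
        if exceeds.to_numpy().any():
            raise ValidationError("positives exceed n_replicates for some event")
        if (positives.to_numpy() < 0).any():
            raise ValidationError("positives must be nonnegative")
        self.positives = positives.astype(int)
        self.events = events
        self.primer_scope = primer_scope

    # -- views ------------------------------------------------------------

    @property
    def incidence(self) -> pd.DataFrame:
        """Boolean species-by-event presence: positives >= 1."""
        return self.positives.ge(1)

    @property
    def species(self) -> list[str]:
        return list(self.positives.index)

    @property
    def event_ids(self) -> list[str]:
        return list(self.positives.columns)

    @property
    def n_events(self) -> int:
        return self.positives.shape[1]

    def species_set(self, event_ids: Iterable[str] | None = None) -> set[str]:
        """Species incident in at least one of the given events (all by default)."""
        sub = self.incidence if event_ids is None else self.incidence[list(event_ids)]
        return set(sub.index[sub.any(axis=1)])

    def subset_events(self, event_ids: Sequence[str]) -> "DetectionMatrix":
        return DetectionMatrix(
            self.positives[list(event_ids)],
            self.events.loc[list(event_ids)],
            self.primer_scope,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"DetectionMatrix({len(self.species)} species x {self.n_events} events, "
            f"scope={self.primer_scope})"
        )

    # -- persistence -------------------------------------------------------

    def write(self, path: str | Path) -> None:
        """Write the matrix as TSV plus a sidecar JSON of event annotations."""
        path = Path(path)
        out = self.positives.copy()
        out.index.name = "species"
        out.to_csv(path, sep="\t")
        sidecar = {
            "primer_scope": self.primer_scope,
            "events": {
                eid: {
                    "location": row["location"],
                    "substrate": row["substrate"],
                    "season": row["season"],
                    "date": row["date"].isoformat()
                    if hasattr(row["date"], "isoformat")
                    else str(row["date"]),
                    "n_replicates": int(row["n_replicates"]),
                }
                for eid, row in self.events.iterrows()
            },
        }
        path.with_suffix(path.suffix + ".events.json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def read(cls, path: str | Path) -> "DetectionMatrix":
        path = Path(path)
        positives = pd.read_csv(path, sep="\t", index_col="species")
        sidecar = json.loads(
            path.with_suffix(path.suffix + ".events.json").read_text()
        )
        events = pd.DataFrame.from_dict(sidecar["events"], orient="index")
        events.index.name = "event_id"
        events["date"] = [_dt.date.fromisoformat(d) for d in events["date"]]
        events = events.loc[list(positives.columns)]
        return cls(positives, events, sidecar["primer_scope"])


# ---------------------------------------------------------------------------
# Readers


def _parse_date(value: str, row: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"row {row}: unparseable date {value!r}") from exc


def read_sample_metadata(path: str | Path, sep: str = "\t") -> list[SampleRecord]:
    """Read and validate the replicate-sample metadata table.

    Required columns: sample_id, location, substrate, season, date,
    replicate_index. Optional: event_id (synthesized from
    location+substrate+date when absent), volume_ml (water only).
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample_id", "location", "substrate", "season", "date",
                "replicate_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate sample_id: {dup.iloc[0]!r}")

    records: list[SampleRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        substrate = str(row.substrate).strip().lower()
        season = str(row.season).strip().lower()
        if substrate not in SUBSTRATES:
            raise ValidationError(f"row {i}: unknown substrate {row.substrate!r}")
        if season not in SEASONS:
            raise ValidationError(f"row {i}: unknown season {row.season!r}")
        date = _parse_date(row.date, i)
        volume = None
        if "volume_ml" in df.columns:
            raw = getattr(row, "volume_ml")
            if raw is not None and str(raw).strip() not in ("", "nan", "NA"):
                volume = float(raw)
        event_id = None
        if "event_id" in df.columns:
            raw = getattr(row, "event_id")
            if raw is not None and str(raw).strip() not in ("", "nan", "NA"):
                event_id = str(raw).strip()
        if event_id is None:
            event_id = synthesize_event_id(str(row.location).strip(), substrate, date)
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id).strip(),
                event_id=event_id,
                location=str(row.location).strip(),
                substrate=substrate,
                season=season,
                date=date,
                replicate_index=int(row.replicate_index),
                volume_ml=volume,
            )
        )
    _check_event_consistency(records)
    return records


def _check_event_consistency(records: Sequence[SampleRecord]) -> None:
    seen: dict[str, tuple] = {}
    for r in records:
        key = (r.location, r.substrate, r.season, r.date)
        if r.event_id in seen and seen[r.event_id] != key:
            raise ValidationError(
                f"event {r.event_id!r} has inconsistent annotations: "
                f"{seen[r.event_id]} vs {key}"
            )
        seen[r.event_id] = key


def read_assignments(path: str | Path, sep: str = "\t") -> list[TaxonDetection]:
    """Read per-sample taxonomic assignments.

    Rows with read_count 0 are dropped (count logged); taxon names are
    whitespace-normalized.
    """
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "taxon_name": str})
    required = {"sample_id", "primer", "taxon_name", "rank", "read_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"assignments missing columns: {sorted(missing)}")
    n_zero = int((df["read_count"].astype(int) == 0).sum())
    if n_zero:
        logger.info("dropping %d zero-read assignment rows", n_zero)
        df = df[df["read_count"].astype(int) > 0]
    return [
        TaxonDetection(
            sample_id=str(r.sample_id).strip(),
            primer=str(r.primer).strip(),
            taxon_name=" ".join(str(r.taxon_name).split()),
            rank=str(r.rank).strip().lower(),
            read_count=int(r.read_count),
        )
        for r in df.itertuples(index=False)
    ]


def write_assignments(
    detections: Sequence[TaxonDetection], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "primer": d.primer,
                "taxon_name": d.taxon_name,
                "rank": d.rank,
                "read_count": d.read_count,
            }
            for d in detections
        ],
        columns=["sample_id", "primer", "taxon_name", "rank", "read_count"],
    ).to_csv(path, sep="\t", index=False)


def write_sample_metadata(
    samples: Sequence[SampleRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "event_id": s.event_id,
                "location": s.location,
                "substrate": s.substrate,
                "season": s.season,
                "date": s.date.isoformat(),
                "replicate_index": s.replicate_index,
                "volume_ml": "" if s.volume_ml is None else s.volume_ml,
            }
            for s in samples
        ],
        columns=["sample_id", "event_id", "location", "substrate", "season",
                 "date", "replicate_index", "volume_ml"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pooling


def build_events(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    """Tabulate sampling events (one row per event_id) from sample records."""
    rows: dict[str, dict] = {}
    for s in samples:
        if s.event_id not in rows:
            rows[s.event_id] = {
                "location": s.location,
                "substrate": s.substrate,
                "season": s.season,
                "date": s.date,
                "n_replicates": 0,
            }
        rows[s.event_id]["n_replicates"] += 1
    events = pd.DataFrame.from_dict(rows, orient="index")
    events.index.name = "event_id"
    return events


def pool_by_event(
    detections: Sequence[TaxonDetection],
    samples: Sequence[SampleRecord],
    primer_scope: str = "combined",
) -> DetectionMatrix:
    """Pool replicate-level detections into a species-by-event matrix.

    A species is incident in an event if at least one replicate of that event
    detects it under the requested primer scope; the cell value counts the
    distinct positive replicates. Under the combined scope a replicate counts
    once if either primer detects the species in it (replicate-level union).

    Genus-rank detections are rejected: taxa must pass the curation filter
    (which resolves or discards them) before pooling.
    """
    if primer_scope not in PRIMER_SCOPES:
        raise ValidationError(f"unknown primer_scope {primer_scope!r}")
    sample_index = {s.sample_id: s for s in samples}
    orphans = sorted({d.sample_id for d in detections} - set(sample_index))
    if orphans:
        raise ValidationError(
            f"detections reference unknown sample_ids: {orphans[:10]}"
        )
    genus_rank = sorted({d.taxon_name for d in detections if d.rank != "species"})
    if genus_rank:
        raise ValidationError(
            "genus-rank detections must be resolved by the curation filter "
            f"before pooling: {genus_rank[:10]}"
        )

    if primer_scope == "combined":
        primers_seen = {d.primer for d in detections}
        if len(primers_seen) == 1:
            warnings.warn(
                f"combined scope requested but input carries a single primer "
                f"({next(iter(primers_seen))}); proceeding",
                stacklevel=2,
            )
        kept = detections
    else:
        kept = [d for d in detections if d.primer == primer_scope]

    events = build_events(samples)
    # distinct positive replicates per (species, event)
    positive: dict[tuple[str, str], set[str]] = {}
    for d in kept:
        s = sample_index[d.sample_id]
        positive.setdefault((d.taxon_name, s.event_id), set()).add(d.sample_id)

    species = sorted({name for name, _ in positive})
    mat = pd.DataFrame(
        np.zeros((len(species), len(events)), dtype=int),
        index=species,
        columns=events.index,
    )
    for (name, eid), reps in positive.items():
        mat.at[name, eid] = len(reps)
    mat.index.name = "species"
    return DetectionMatrix(mat, events, primer_scope)
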