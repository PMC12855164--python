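"""Occurrence-based curation of taxonomic assignments.

Metabarcoding classifiers assign reads to whatever reference sequence matches
best, which in regions with sparse reference coverage routinely yields labels
for species never recorded in the study region. This module implements a
plausibility filter against a regional occurrence catalog: each distinct
assigned taxon is accepted, reassigned to a documented congener, or excluded,
and every decision is recorded in an audit table.

Decision precedence, applied in order:

1. blocklist (domestic animals, humans, anthropogenic food contaminants)
   -> exclude;
2. explicit override (curated relabeling, e.g. *Canis lupus* ->
   *Lupulella mesomelas* where the regional canid lacks reference coverage)
   -> reassign;
3. species-rank label documented in the region -> accept;
4. otherwise resolve the documented congeners of the label's genus: exactly
   one candidate -> reassign to it; none -> exclude; several -> exclude as
   ambiguous.

Step 4's candidate set depends on ``ambiguity_mode``: either all documented
congeners count (``documented_congener_unique``), or only documented congeners
that lack a marker reference sequence (``unreferenced_congener_unique``) — the
latter models the mechanism of misassignment, where the true source species
cannot match because it has no reference to match to.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .io_model import TaxonDetection

logger = logging.getLogger(__name__)

AMBIGUITY_MODES = ("documented_congener_unique", "unreferenced_congener_unique")
ACTIONS = ("accept", "reassign", "exclude")
REASONS = (
    "documented",
    "override",
    "unique_congener",
    "ambiguous_congeners",
    "no_congener",
    "blocklisted",
    "anthropogenic",
)


def canonicalize_name(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Normalize a taxon name: collapse whitespace, truncate trinomials to the
    binomial, apply the synonym alias table."""
    parts = name.split()
    if len(parts) >= 2:
        parts = parts[:2]
    canon = " ".join(parts)
    if canon:
        canon = canon[0].upper() + canon[1:]
    if aliases and canon in aliases:
        canon = aliases[canon]
    return canon


def genus_of(name: str) -> str | None:
    parts = name.split()
    return parts[0] if parts and parts[0][0].isupper() else None


@dataclass
class OccurrenceCatalog:
    """Documented species of the study region, indexed by genus."""

    documented_species: set[str]
    genus_index: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genus_index:
            idx: dict[str, list[str]] = {}
            for sp in sorted(self.documented_species):
                g = genus_of(sp)
                if g is None:
                    raise ValueError(f"cannot parse genus of {sp!r}")
                idx.setdefault(g, []).append(sp)
            self.genus_index = idx
        listed = [sp for sps in self.genus_index.values() for sp in sps]
        if len(listed) != len(set(listed)):
            dup = [s for s, c in Counter(listed).items() if c > 1]
            raise ValueError(f"species under multiple genera: {dup}")

    def congeners(self, genus: str) -> list[str]:
        return list(self.genus_index.get(genus, []))

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrenceCatalog":
        """Load from CSV with columns species,genus,documented (documented is
        a 0/1 or true/false flag; undocumented rows are catalog context only)."""
        df = pd.read_csv(path)
        required = {"species", "documented"}
        if missing := required - set(df.columns):
            raise ValueError(f"occurrence catalog missing columns {sorted(missing)}")
        flag = df["documented"].astype(str).str.lower().isin(("1", "true", "yes"))
        documented = {
            canonicalize_name(s) for s in df.loc[flag, "species"].astype(str)
        }
        return cls(documented_species=documented)


@dataclass
class ReferenceCatalog:
    """Per-species marker reference availability.

    ``has_reference`` returns True/False for listed species and None for
    species absent from the catalog ("unknown", distinct from False).
    """

    _table: dict[str, bool]

    def has_reference(self, species: str) -> bool | None:
        return self._table.get(species)

    def lacks_reference(self, species: str) -> bool:
        # Absence from the marker listing is the operative condition: an
        # unlisted species has no record to match against.
        return self._table.get(species) is not True

    @classmethod
    def from_mapping(cls, table: Mapping[str, bool]) -> "ReferenceCatalog":
        return cls({canonicalize_name(k): bool(v) for k, v in table.items()})

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceCatalog":
        """Load from CSV with columns species,has_reference (optionally a
        marker column; rows are pooled across markers by any-true)."""
        df = pd.read_csv(path)
        if missing := {"species", "has_reference"} - set(df.columns):
            raise ValueError(f"reference catalog missing columns {sorted(missing)}")
        flag = df["has_reference"].astype(str).str.lower().isin(("1", "true", "yes"))
        table: dict[str, bool] = {}
        for sp, has in zip(df["species"].astype(str), flag):
            key = canonicalize_name(sp)
            table[key] = table.get(key, False) or bool(has)
        return cls(table)


@dataclass
class CurationRules:
    """Blocklist, overrides, synonym aliases, and the ambiguity criterion."""

    blocklist: set[str] = field(default_factory=set)
    anthropogenic: set[str] = field(default_factory=set)
    overrides: dict[str, str] = field(default_factory=dict)
    override_notes: dict[str, str] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)
    ambiguity_mode: str = "documented_congener_unique"

    def __post_init__(self) -> None:
        if self.ambiguity_mode not in AMBIGUITY_MODES:
            raise ValueError(f"unknown ambiguity_mode {self.ambiguity_mode!r}")
        clash = (self.blocklist | self.anthropogenic) & set(self.overrides)
        if clash:
            raise ValueError(f"blocklist and overrides overlap: {sorted(clash)}")

    def validate_against(self, occ: OccurrenceCatalog) -> None:
        bad = [t for t in self.overrides.values()
               if t not in occ.documented_species]
        if bad:
            raise ValueError(f"override targets not documented: {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CurationRules":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        overrides = {}
        notes = {}
        for k, v in (raw.get("overrides") or {}).items():
            if isinstance(v, dict):
                overrides[canonicalize_name(k)] = canonicalize_name(v["final"])
                notes[canonicalize_name(k)] = v.get("justification", "")
            else:
                overrides[canonicalize_name(k)] = canonicalize_name(v)
        return cls(
            blocklist={canonicalize_name(n) for n in raw.get("blocklist") or []},
            anthropogenic={
                canonicalize_name(n) for n in raw.get("anthropogenic") or []
            },
            overrides=overrides,
            override_notes=notes,
            aliases={
                canonicalize_name(k): canonicalize_name(v)
                for k, v in (raw.get("aliases") or {}).items()
            },
            ambiguity_mode=raw.get("ambiguity_mode", "documented_congener_unique"),
        )


@dataclass(frozen=True)
class FilterDecision:
    """Audit row: the fate of one distinct assigned taxon."""

    original_name: str
    original_rank: str
    action: str
    reason_code: str
    final_name: str | None
    n_congeners_documented: int
    n_congeners_unreferenced: int

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.reason_code not in REASONS:
            raise ValueError(f"unknown reason {self.reason_code!r}")
        if self.action == "exclude" and self.final_name is not None:
            raise ValueError("excluded taxon must not carry final_name")
        if self.action != "exclude" and self.final_name is None:
            raise ValueError("retained taxon must carry final_name")
        if self.action == "accept" and self.final_name != self.original_name:
            raise ValueError("accept must keep the original name")


def classify_taxon(
    name: str,
    rank: str,
    occ: OccurrenceCatalog,
    ref: ReferenceCatalog,
    rules: CurationRules,
) -> FilterDecision:
    """Apply the curation decision procedure to one assigned taxon.

    Pure function: identical inputs yield identical decisions. ``name`` is
    canonicalized (binomial truncation, alias table) before lookup.
    """
    if not occ.documented_species:
        raise ValueError("occurrence catalog is empty")
    if rank not in ("species", "genus"):
        raise ValueError(f"unknown rank {rank!r}")
    canon = canonicalize_name(name, rules.aliases)
    genus = canon if rank == "genus" else genus_of(canon)

    congeners = occ.congeners(genus) if genus else []
    if rank == "species" and canon in congeners:
        # a documented species never counts as its own reassignment candidate
        congeners = [c for c in congeners if c != canon]
    unreferenced = [c for c in congeners if ref.lacks_reference(c)]
    counts = dict(
        n_congeners_documented=len(congeners),
        n_congeners_unreferenced=len(unreferenced),
    )

    if canon in rules.blocklist:
        return FilterDecision(canon, rank, "exclude", "blocklisted", None, **counts)
    if canon in rules.anthropogenic:
        return FilterDecision(canon, rank, "exclude", "anthropogenic", None, **counts)
    if canon in rules.overrides:
        return FilterDecision(
            canon, rank, "reassign", "override", rules.overrides[canon], **counts
        )
    if rank == "species" and canon in occ.documented_species:
        return FilterDecision(canon, rank, "accept", "documented", canon, **counts)
    if genus is None:
        logger.warning("cannot parse genus from %r; excluding", name)
        return FilterDecision(canon, rank, "exclude", "no_congener", None, **counts)

    candidates = (
        congeners
        if rules.ambiguity_mode == "documented_congener_unique"
        else unreferenced
    )
    if len(candidates) == 1:
        return FilterDecision(
            canon, rank, "reassign", "unique_congener", candidates[0], **counts
        )
    if len(candidates) == 0:
        return FilterDecision(canon, rank, "exclude", "no_congener", None, **counts)
    return FilterDecision(
        canon, rank, "exclude", "ambiguous_congeners", None, **counts
    )


def apply_filter(
    detections: Sequence[TaxonDetection],
    occ: OccurrenceCatalog,
    ref: ReferenceCatalog,
    rules: CurationRules,
) -> tuple[list[TaxonDetection], list[FilterDecision]]:
    """Filter a detection table, returning retained detections and the audit.

    Each distinct (name, rank) receives exactly one decision. Detections of
    excluded taxa are dropped; reassigned names are substituted; detections
    that converge on the same final species within a sample+primer are merged
    with read counts summed.
    """
    audit: dict[tuple[str, str], FilterDecision] = {}
    merged: dict[tuple[str, str, str], int] = {}
    for d in detections:
        canon = canonicalize_name(d.taxon_name, rules.aliases)
        key = (canon, d.rank)
        if key not in audit:
            audit[key] = classify_taxon(d.taxon_name, d.rank, occ, ref, rules)
        decision = audit[key]
        if decision.action == "exclude":
            continue
        mkey = (d.sample_id, d.primer, decision.final_name)
        merged[mkey] = merged.get(mkey, 0) + d.read_count
    filtered = [
        TaxonDetection(sample_id=sid, primer=primer, taxon_name=name,
                       rank="species", read_count=reads)
        for (sid, primer, name), reads in merged.items()
    ]
    return filtered, list(audit.values())


def summarize_decisions(audit: Sequence[FilterDecision]) -> pd.DataFrame:
    """Tally the audit by (action, reason_code); counts sum to len(audit)."""
    if not audit:
        raise ValueError("audit is empty")
    counts = Counter((d.action, d.reason_code) for d in audit)
    df = pd.DataFrame(
        [
            {"action": a, "reason_code": r, "n_taxa": n}
            for (a, r), n in sorted(counts.items())
        ]
    )
    return df


def write_audit(audit: Sequence[FilterDecision], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "original_name": d.original_name,
                "original_rank": d.original_rank,
                "action": d.action,
                "reason_code": d.reason_code,
                "final_name": "" if d.final_name is None else d.final_name,
                "n_congeners_documented": d.n_congeners_documented,
                "n_congeners_unreferenced": d.n_congeners_unreferenced,
            }
            for d in audit
        ],
        columns=[
            "original_name", "original_rank", "action", "reason_code",
            "final_name", "n_congeners_documented", "n_congeners_unreferenced",
        ],
    ).to_csv(path, sep="\t", index=False)


def default_rules() -> CurationRules:
    """Rules shipped as a worked example: domestic/human blocklist, food
    contaminants, and the jackal override for a canid lacking reference
    coverage."""
    return CurationRules(
        blocklist={"Homo sapiens", "Bos taurus", "Ovis aries", "Capra hircus",
                   "Sus scrofa", "Felis catus", "Gallus gallus"},
        anthropogenic={"Thunnus albacares", "Salmo salar"},
        overrides={"Canis lupus": "Lupulella mesomelas"},
        override_notes={
            "Canis lupus": "abundant native black-backed jackal with a single "
            "marker reference; domestic-dog label implausible in-reserve"
        },
        aliases={"Canis mesomelas": "Lupulella mesomelas"},
    )
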