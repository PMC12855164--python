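"""Curation decision procedure: worked cases, oracle agreement, precedence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ednasurvey.taxon_filter import (
    CurationRules,
    OccurrenceCatalog,
    ReferenceCatalog,
    apply_filter,
    canonicalize_name,
    classify_taxon,
    default_rules,
    summarize_decisions,
    write_audit,
)

from conftest import det


@pytest.fixture
def occ():
    return OccurrenceCatalog(documented_species={
        "Lupulella mesomelas",
        "Tragelaphus oryx", "Tragelaphus strepsiceros", "Tragelaphus angasii",
        "Genusx alpha",
        "Anas undulata", "Anas erythrorhyncha", "Anas capensis",
        "Equus quagga",
    })


@pytest.fixture
def ref():
    return ReferenceCatalog.from_mapping({
        "Lupulella mesomelas": True,
        "Tragelaphus oryx": True,
        "Tragelaphus strepsiceros": True,
        "Tragelaphus angasii": True,
        "Genusx alpha": False,
        "Anas undulata": False,
        "Anas erythrorhyncha": False,
        "Anas capensis": True,
        "Equus quagga": True,
    })


@pytest.fixture
def rules():
    return default_rules()


class TestClassifyTaxon:
    def test_anthropogenic_contaminant_excluded(self, occ, ref, rules):
        d = classify_taxon("Thunnus albacares", "species", occ, ref, rules)
        assert (d.action, d.reason_code) == ("exclude", "anthropogenic")

    def test_domestic_blocklisted(self, occ, ref, rules):
        d = classify_taxon("Bos taurus", "species", occ, ref, rules)
        assert (d.action, d.reason_code) == ("exclude", "blocklisted")

    def test_override_reassigns_wolf_label_to_jackal(self, occ, ref, rules):
        d = classify_taxon("Canis lupus", "species", occ, ref, rules)
        assert (d.action, d.reason_code) == ("reassign", "override")
        assert d.final_name == "Lupulella mesomelas"

    def test_documented_species_accepted(self, occ, ref, rules):
        d = classify_taxon("Equus quagga", "species", occ, ref, rules)
        assert (d.action, d.reason_code) == ("accept", "documented")
        assert d.final_name == "Equus quagga"

    def test_genus_with_single_documented_species_reassigned(
        self, occ, ref, rules
    ):
        d = classify_taxon("Genusx", "genus", occ, ref, rules)
        assert (d.action, d.reason_code) == ("reassign", "unique_congener")
        assert d.final_name == "Genusx alpha"
        assert d.n_congeners_documented == 1

    def test_nondocumented_species_with_three_congeners_ambiguous(
        self, occ, ref, rules
    ):
        d = classify_taxon("Tragelaphus imberbis", "species", occ, ref, rules)
        assert (d.action, d.reason_code) == ("exclude", "ambiguous_congeners")
        assert d.n_congeners_documented == 3

    def test_no_congener_excluded(self, occ, ref, rules):
        d = classify_taxon("Loxodonta africana", "species", occ, ref, rules)
        assert (d.action, d.reason_code) == ("exclude", "no_congener")
        assert d.n_congeners_documented == 0

    def test_unreferenced_mode_uses_reference_gaps(self, occ, ref, rules):
        # Anas: 3 documented congeners, 2 lacking references -> still
        # ambiguous under both modes
        d = classify_taxon("Anas platyrhynchos", "species", occ, ref,
                           rules)
        assert d.reason_code == "ambiguous_congeners"
        assert d.n_congeners_unreferenced == 2
        # Tragelaphus with one reference gap: ambiguous among documented,
        # unique among unreferenced
        ref2 = ReferenceCatalog.from_mapping({
            "Tragelaphus oryx": True, "Tragelaphus strepsiceros": True,
            "Tragelaphus angasii": False,
        })
        narrow = CurationRules(ambiguity_mode="unreferenced_congener_unique")
        d2 = classify_taxon("Tragelaphus imberbis", "species", occ, ref2,
                            narrow)
        assert (d2.action, d2.final_name) == ("reassign", "Tragelaphus angasii")

    def test_trinomial_truncated_and_alias_applied(self, occ, ref, rules):
        d = classify_taxon("Equus quagga burchellii", "species", occ, ref, rules)
        assert d.action == "accept" and d.final_name == "Equus quagga"
        d2 = classify_taxon("Canis mesomelas", "species", occ, ref, rules)
        assert d2.final_name == "Lupulella mesomelas"

    def test_empty_catalog_errors(self, ref, rules):
        with pytest.raises(ValueError, match="empty"):
            classify_taxon("Equus quagga", "species",
                           OccurrenceCatalog(documented_species=set()),
                           ref, rules)

    def test_deterministic(self, occ, ref, rules):
        a = classify_taxon("Anas platyrhynchos", "species", occ, ref, rules)
        b = classify_taxon("Anas platyrhynchos", "species", occ, ref, rules)
        assert a == b


def oracle_decision(name, rank, documented, has_ref, blocklist, anthropogenic,
                    overrides, mode):
    """Independent re-derivation of the decision table as flat conditionals."""
    words = name.split()[:2]
    canon = " ".join(words)
    if canon in blocklist:
        return ("exclude", "blocklisted", None)
    if canon in anthropogenic:
        return ("exclude", "anthropogenic", None)
    if canon in overrides:
        return ("reassign", "override", overrides[canon])
    if rank == "species" and canon in documented:
        return ("accept", "documented", canon)
    genus = canon.split()[0]
    congeners = sorted(s for s in documented
                       if s.split()[0] == genus and s != canon)
    if mode == "documented_congener_unique":
        candidates = congeners
    else:
        candidates = [s for s in congeners if not has_ref.get(s, False)]
    if len(candidates) == 1:
        return ("reassign", "unique_congener", candidates[0])
    if len(candidates) == 0:
        return ("exclude", "no_congener", None)
    return ("exclude", "ambiguous_congeners", None)


@pytest.mark.parametrize("mode", ["documented_congener_unique",
                                  "unreferenced_congener_unique"])
def test_randomized_catalogs_agree_with_oracle(mode):
    """classify_taxon matches a brute-force rule re-derivation on random
    catalogs, queried with documented, non-documented, and genus labels."""
    rng = np.random.default_rng(2024)
    genera = [f"Gen{i:02d}" for i in range(12)]
    for trial in range(300):
        documented = set()
        has_ref = {}
        for g in genera:
            for j in range(int(rng.integers(0, 4))):
                sp = f"{g} sp{j}"
                documented.add(sp)
                has_ref[sp] = bool(rng.random() < 0.5)
        if not documented:
            continue
        pool = sorted(documented)
        blocklist = set(rng.choice(pool, size=min(2, len(pool)), replace=False))
        override_src = f"{genera[0]} foreign"
        overrides = {override_src: pool[0]} if pool[0] not in blocklist else {}
        occ = OccurrenceCatalog(documented_species=documented)
        ref = ReferenceCatalog.from_mapping(has_ref)
        rules = CurationRules(blocklist=blocklist, overrides=overrides,
                              ambiguity_mode=mode)
        queries = [(pool[int(rng.integers(0, len(pool)))], "species"),
                   (f"{genera[int(rng.integers(0, 12))]} novel", "species"),
                   (genera[int(rng.integers(0, 12))], "genus"),
                   (override_src, "species")]
        for name, rank in queries:
            got = classify_taxon(name, rank, occ, ref, rules)
            want = oracle_decision(name, rank, documented, has_ref,
                                   blocklist, set(), overrides, mode)
            assert (got.action, got.reason_code, got.final_name) == want, (
                f"trial {trial}: {name} ({rank})"
            )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    species_idx=st.integers(0, 5),
    blocklisted=st.booleans(),
    overridden=st.booleans(),
    documented=st.booleans(),
)
def test_blocklist_precedence_dominates(species_idx, blocklisted, overridden,
                                        documented):
    """Adding a name to the blocklist always yields exclusion, whatever the
    override/catalog status of the name."""
    name = f"Gen00 sp{species_idx}"
    doc = {"Gen00 target"} | ({name} if documented else set())
    occ = OccurrenceCatalog(documented_species=doc)
    ref = ReferenceCatalog.from_mapping({})
    overrides = {name: "Gen00 target"} if overridden and not blocklisted else {}
    rules = CurationRules(
        blocklist={name} if blocklisted else set(), overrides=overrides
    )
    d = classify_taxon(name, "species", occ, ref, rules)
    if blocklisted:
        assert (d.action, d.reason_code) == ("exclude", "blocklisted")
    elif overridden:
        assert (d.action, d.reason_code) == ("reassign", "override")
    elif documented:
        assert d.action == "accept"


class TestApplyFilter:
    def test_single_documented_species_passes_through(self, occ, ref, rules):
        rows = [det("s1", "Equus quagga")]
        filtered, audit = apply_filter(rows, occ, ref, rules)
        assert filtered == rows
        assert len(audit) == 1 and audit[0].action == "accept"

    def test_convergent_reassignments_merge_reads(self, occ, ref, rules):
        # wolf label (override) and jackal synonym (alias) converge in one sample
        rows = [det("s1", "Canis lupus", reads=10),
                det("s1", "Canis mesomelas", reads=5)]
        filtered, audit = apply_filter(rows, occ, ref, rules)
        assert len(filtered) == 1
        assert filtered[0].taxon_name == "Lupulella mesomelas"
        assert filtered[0].read_count == 15

    def test_empty_input_empty_outputs(self, occ, ref, rules):
        assert apply_filter([], occ, ref, rules) == ([], [])

    def test_read_conservation_reconciles_with_audit(self, occ, ref, rules):
        rows = [det("s1", "Equus quagga", reads=10),
                det("s2", "Thunnus albacares", reads=7),
                det("s1", "Tragelaphus imberbis", reads=3),
                det("s2", "Canis lupus", reads=4)]
        filtered, audit = apply_filter(rows, occ, ref, rules)
        total_in = sum(r.read_count for r in rows)
        total_out = sum(r.read_count for r in filtered)
        excluded_names = {d.original_name for d in audit
                          if d.action == "exclude"}
        excluded_reads = sum(
            r.read_count for r in rows
            if canonicalize_name(r.taxon_name, rules.aliases) in excluded_names
        )
        assert total_in == total_out + excluded_reads

    def test_one_decision_per_distinct_taxon(self, occ, ref, rules):
        rows = [det(f"s{i}", "Equus quagga") for i in range(5)]
        rows += [det(f"s{i}", "Anas platyrhynchos") for i in range(3)]
        _, audit = apply_filter(rows, occ, ref, rules)
        assert len(audit) == 2


class TestSummarizeDecisions:
    def test_counts_and_idempotence(self, occ, ref, rules):
        rows = [det("s1", "Equus quagga"), det("s1", "Genusx alpha"),
                det("s2", "Thunnus albacares")]
        _, audit = apply_filter(rows, occ, ref, rules)
        t1 = summarize_decisions(audit)
        t2 = summarize_decisions(audit)
        assert t1.equals(t2)
        assert t1["n_taxa"].sum() == len(audit)

    def test_all_accepts(self, occ, ref, rules):
        rows = [det("s1", "Equus quagga"), det("s2", "Anas capensis"),
                det("s3", "Tragelaphus oryx")]
        _, audit = apply_filter(rows, occ, ref, rules)
        table = summarize_decisions(audit)
        assert len(table) == 1
        assert table.iloc[0]["action"] == "accept"
        assert table.iloc[0]["n_taxa"] == 3

    def test_empty_audit_errors(self):
        with pytest.raises(ValueError):
            summarize_decisions([])


def test_audit_writes_tabular_trail(tmp_path, occ, ref, rules):
    rows = [det("s1", "Equus quagga"), det("s2", "Canis lupus")]
    _, audit = apply_filter(rows, occ, ref, rules)
    write_audit(audit, tmp_path / "audit.tsv")
    back = pd.read_csv(tmp_path / "audit.tsv", sep="\t")
    assert set(back["action"]) == {"accept", "reassign"}
    assert "n_congeners_documented" in back.columns
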