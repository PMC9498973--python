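import numpy as np
import pytest

from barcodekit.seqio import SequenceError
from barcodekit.sites import (
    SitePolicy,
    classify_sites,
    diagnostic_sites,
    identify_sample,
    key_from_dict,
    key_to_dict,
    variable_site_count,
)
from barcodekit.synth import SimulationConfig, simulate_dataset
from conftest import make_alignment, make_metadata


def test_identical_rows_have_no_variable_sites():
    aln = make_alignment({f"r{i}": "ACGTACGT" for i in range(4)})
    report = classify_sites(aln)
    assert variable_site_count(report) == 0
    assert set(report["class"]) == {"invariant"}


def test_planted_substitutions_counted_exactly(rng):
    base = "".join(rng.choice(list("ACGT"), size=80))
    rows = {f"r{i}": base for i in range(6)}
    planted = sorted(rng.choice(80, size=7, replace=False))
    mutated = list(base)
    for pos in planted:
        mutated[pos] = "ACGT"[("ACGT".index(mutated[pos]) + 1) % 4]
    rows["mut"] = "".join(mutated)
    report = classify_sites(make_alignment(rows))
    assert variable_site_count(report) == 7
    found = report.loc[report["class"] != "invariant", "position"].tolist()
    assert found == [p + 1 for p in planted]
    # one mutant row only: singleton variants, not parsimony-informative
    assert set(report.loc[report["class"] != "invariant", "class"]) == {"variable"}


def test_parsimony_informative_requires_two_by_two():
    aln = make_alignment({"a": "AA", "b": "AA", "c": "GA", "d": "GA"})
    report = classify_sites(aln)
    assert report.loc[0, "class"] == "parsimony-informative"
    assert report.loc[1, "class"] == "invariant"


def test_classification_invariant_to_row_order_and_invariant_padding():
    rows = {"a": "ACGT", "b": "ACAT", "c": "GCGT"}
    n1 = variable_site_count(classify_sites(make_alignment(rows)))
    reordered = {k: rows[k] for k in ("c", "a", "b")}
    n2 = variable_site_count(classify_sites(make_alignment(reordered)))
    padded = {k: v + "TTTT" for k, v in rows.items()}
    n3 = variable_site_count(classify_sites(make_alignment(padded)))
    assert n1 == n2 == n3


def test_outgroup_rows_excluded_by_default():
    species = {"a": "sp1", "b": "sp1", "og": "out"}
    aln = make_alignment({"a": "ACGT", "b": "ACGT", "og": "TTTT"}, species)
    meta = make_metadata(species, outgroup="out")
    assert variable_site_count(classify_sites(aln, meta)) == 0
    assert variable_site_count(classify_sites(aln, meta, include_outgroup=True)) == 3


def test_two_fixed_species_are_mutually_diagnostic(two_species_alignment):
    aln, meta = two_species_alignment
    key = diagnostic_sites(aln, meta)
    assert key.sites["spx"] == [(3, "A")]
    assert key.sites["spy"] == [(3, "G")]
    # disjoint at the (position, state) level
    assert set(key.sites["spx"]).isdisjoint(key.sites["spy"])


def test_polymorphic_species_has_no_diagnostic_there():
    species = {"x1": "spx", "x2": "spx", "y1": "spy"}
    aln = make_alignment({"x1": "AAT", "x2": "GAT", "y1": "CAT"}, species)
    key = diagnostic_sites(aln, make_metadata(species))
    assert key.sites["spx"] == []
    assert key.sites["spy"] == [(1, "C")]
    assert "spy" in key.low_confidence  # single row


def test_ambiguity_policy_is_conservative():
    # R = A or G: ambiguity inside the candidate species disqualifies;
    # ambiguity elsewhere disqualifies when it may contain the state
    species = {"x1": "spx", "x2": "spx", "y1": "spy", "y2": "spy"}
    aln = make_alignment(
        {"x1": "AC", "x2": "RC", "y1": "GC", "y2": "GC"}, species
    )
    key = diagnostic_sites(aln, make_metadata(species))
    assert key.sites["spx"] == []  # own ambiguity
    assert key.sites["spy"] == []  # R might be G
    aln2 = make_alignment(
        {"x1": "AC", "x2": "AC", "y1": "YC", "y2": "TC"}, species
    )
    key2 = diagnostic_sites(aln2, make_metadata(species))
    assert key2.sites["spx"] == [(1, "A")]  # Y = C/T cannot be A


def test_gap_handling_in_diagnostics():
    species = {"x1": "spx", "x2": "spx", "y1": "spy", "y2": "spy"}
    aln = make_alignment(
        {"x1": "A-C", "x2": "A-C", "y1": "AAC", "y2": "AAC"}, species
    )
    default = diagnostic_sites(aln, make_metadata(species))
    # gap is not a diagnostic state by default, but a gap in the *other*
    # species counts as a different state
    assert default.sites["spx"] == []
    assert default.sites["spy"] == [(2, "A")]
    allowed = diagnostic_sites(
        aln, make_metadata(species), SitePolicy(allow_indel_diagnostics=True)
    )
    assert allowed.sites["spx"] == [(2, "-")]


def test_monotonicity_under_taxon_deletion():
    cfg = SimulationConfig(
        n_species=4,
        samples_per_species=(6, 6, 6, 6),
        haplotypes_per_species=(2, 2, 2, 2),
        n_diagnostic_per_species=(2, 2, 2, 2),
        ambiguity_rate=0.0,
        indel_rate=0.0,
        seed=9,
    )
    ds = simulate_dataset(cfg)
    full = diagnostic_sites(ds.alignment, ds.metadata)
    dropped_sp = cfg.species_names[0]
    keep = [m for m in ds.metadata if m.species != dropped_sp]
    keep_aln = ds.alignment.subset([m.sample_id for m in keep])
    reduced = diagnostic_sites(keep_aln, keep)
    for sp in cfg.species_names[1:]:
        assert set(full.sites[sp]) <= set(reduced.sites[sp])


def test_identify_sample_calls(two_species_alignment):
    aln, meta = two_species_alignment
    key = diagnostic_sites(aln, meta)
    call, matched = identify_sample("ACATG", key)
    assert call == "spx" and matched["spx"] == [(3, "A")]
    assert identify_sample("N" * 5, key)[0] == "no-call"
    with pytest.raises(SequenceError):
        identify_sample("ACA", key, alignment_length=5)


def test_identify_on_synthetic_truth():
    cfg = SimulationConfig(
        n_species=3,
        samples_per_species=(8, 8, 8),
        haplotypes_per_species=(3, 2, 2),
        n_diagnostic_per_species=(3, 3, 3),
        ambiguity_rate=0.0,
        seed=4,
    )
    ds = simulate_dataset(cfg)
    key = diagnostic_sites(ds.alignment, ds.metadata)
    for rec in ds.alignment.records:
        expected = ds.truth.sample_species[rec.id]
        if expected == cfg.outgroup_name:
            continue
        call, _ = identify_sample(rec.seq, key, ds.alignment.length)
        assert call == expected


def test_key_json_round_trip(two_species_alignment):
    aln, meta = two_species_alignment
    key = diagnostic_sites(aln, meta)
    back = key_from_dict(key_to_dict(key))
    assert back.sites == key.sites
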