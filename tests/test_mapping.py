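"""Mapper behaviour: exact placements, thresholds, tie-breaks, oracle parity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from satcen._seq import revcomp
from satcen.mapping import MapperConfig, ReadMapper, align_read, map_readset
from satcen.panel import PanelEntry, ReferencePanel

from conftest import mutate_seq, random_seq
from oracle import brute_force_align


@pytest.fixture(scope="module")
def toy_panel(request):
    rng = np.random.default_rng(42)
    return ReferencePanel(
        [
            PanelEntry("satX", random_seq(rng, 221), is_tandem=True),
            PanelEntry("satY", random_seq(rng, 137), is_tandem=True),
            PanelEntry("lineZ", random_seq(rng, 300), is_tandem=False),
        ]
    )


def test_exact_substring_hits_with_identity_one(toy_panel):
    mono = toy_panel["satX"].sequence
    hit = align_read(mono[37:87], toy_panel)
    assert hit is not None
    assert hit.entry == "satX"
    assert hit.identity == 1.0
    assert hit.offset == 37
    assert hit.strand == "+"
    assert not hit.ambiguous


def test_junction_read_maps_on_dimer():
    """A read straddling the monomer junction places on the dimer with
    identity 1.0 at offset monomer_length - overhang."""
    rng = np.random.default_rng(3)
    mono = random_seq(rng, 221)
    panel = ReferencePanel([PanelEntry("sat", mono, is_tandem=True)])
    read = mono[-25:] + mono[:25]
    hit = align_read(read, panel)
    assert hit is not None
    assert (hit.offset, hit.identity, hit.strand) == (196, 1.0, "+")
    assert hit.monomer_offset == 196


def test_reads_below_identity_threshold_are_rejected(toy_panel, rng):
    mono = toy_panel["satX"].sequence[:60]
    # flip 25 % of positions deterministically: every 4th base
    bad = "".join(
        "ACGT"[("ACGT".index(b) + 1) % 4] if i % 4 == 0 else b for i, b in enumerate(mono)
    )
    assert align_read(bad, toy_panel, MapperConfig(min_identity=0.80)) is None
    assert align_read(bad, toy_panel, MapperConfig(min_identity=0.70)) is not None


def test_strand_symmetry(toy_panel, rng):
    for _ in range(20):
        entry = toy_panel.entries[int(rng.integers(0, 3))]
        start = int(rng.integers(0, entry.monomer_length - 40))
        read = mutate_seq(rng, entry.target[start : start + 40], 0.05)
        fwd = align_read(read, toy_panel)
        rev = align_read(revcomp(read), toy_panel)
        assert fwd is not None and rev is not None
        assert fwd.entry == rev.entry
        assert fwd.identity == rev.identity
        assert {fwd.strand, rev.strand} == {"+", "-"}


def test_mapped_count_monotone_in_identity_threshold(toy_panel, rng):
    reads = []
    for i in range(150):
        entry = toy_panel.entries[int(rng.integers(0, 3))]
        start = int(rng.integers(0, entry.monomer_length - 50))
        reads.append((f"r{i}", mutate_seq(rng, entry.target[start : start + 50], rng.uniform(0, 0.4))))
    counts = []
    for thr in (0.95, 0.9, 0.8, 0.7, 0.6):
        _, summary = map_readset(reads, toy_panel, MapperConfig(min_identity=thr))
        counts.append(summary.mapped)
    assert counts == sorted(counts)


def test_tied_entries_flagged_ambiguous_and_resolve_to_panel_order():
    rng = np.random.default_rng(8)
    mono = random_seq(rng, 100)
    panel = ReferencePanel(
        [PanelEntry("first", mono, is_tandem=False), PanelEntry("second", mono, is_tandem=False)]
    )
    hit = align_read(mono[10:60], panel)
    assert hit.entry == "first"
    assert hit.ambiguous


def test_empty_readset_yields_zero_summary(toy_panel):
    hits, summary = map_readset([], toy_panel)
    assert hits == []
    assert (summary.total_reads, summary.mapped, summary.unmapped) == (0, 0, 0)
    assert all(v == 0 for v in summary.per_entry.values())


def test_invalid_symbols_raise_and_all_n_reads_do_not_map(toy_panel):
    with pytest.raises(ValueError, match="non-ACGTN"):
        align_read("ACGTXACGT", toy_panel)
    assert align_read("N" * 50, toy_panel) is None


def test_read_longer_than_every_target_is_unmapped(toy_panel, rng):
    hits, summary = map_readset([("long", random_seq(rng, 2000))], toy_panel)
    assert hits == []
    assert summary.total_reads == 1 and summary.unmapped == 1


def test_per_entry_counts_sum_to_mapped(toy_panel, rng):
    reads = []
    for i in range(300):
        entry = toy_panel.entries[int(rng.integers(0, 3))]
        start = int(rng.integers(0, entry.monomer_length - 50))
        reads.append((f"r{i}", mutate_seq(rng, entry.target[start : start + 50], 0.1)))
    hits, summary = map_readset(reads, toy_panel)
    assert sum(summary.per_entry.values()) == summary.mapped == len(hits)


def test_unique_source_reads_all_assign_to_their_family(small_cfg, small_panel):
    """Error-free reads sampled from one family map 100 % to that family."""
    rng = np.random.default_rng(12)
    mono = small_panel["cen_sat"].sequence
    array = mono * 30
    reads = []
    for i in range(500):
        start = int(rng.integers(0, len(array) - 100))
        reads.append((f"r{i}", array[start : start + 100]))
    hits, summary = map_readset(reads, small_panel)
    assert summary.mapped == 500
    assert summary.per_entry["cen_sat"] == 500
    assert all(h.identity == 1.0 for h in hits)  # dimer trick: no junction blind spot
    assert all(0 <= h.monomer_offset < 221 for h in hits)


@pytest.mark.parametrize("allow_indels", [False])
def test_mapper_equals_bruteforce_oracle_on_random_reads(allow_indels):
    """The production scorer reproduces an exhaustive naive aligner,
    including tie-breaking, identities, offsets and ambiguity flags."""
    rng = np.random.default_rng(99)
    panel = ReferencePanel(
        [
            PanelEntry("a", random_seq(rng, 120), is_tandem=True),
            PanelEntry("b", random_seq(rng, 97), is_tandem=True),
            PanelEntry("c", random_seq(rng, 150), is_tandem=False),
        ]
    )
    cfg = MapperConfig(min_identity=0.8, allow_indels=allow_indels)
    reads = []
    for i in range(300):
        kind = i % 3
        if kind == 0:
            reads.append((f"r{i}", random_seq(rng, 40)))
        else:
            entry = panel.entries[int(rng.integers(0, 3))]
            start = int(rng.integers(0, len(entry.target) - 40))
            reads.append((f"r{i}", mutate_seq(rng, entry.target[start : start + 40], rng.uniform(0, 0.3))))
    hits, _ = map_readset(reads, panel, cfg)
    got = {h.read_id: h for h in hits}
    for rid, seq in reads:
        expected = brute_force_align(seq, panel, cfg.min_identity)
        if expected is None:
            assert rid not in got
        else:
            h = got[rid]
            assert (h.entry, h.offset, h.strand, h.ambiguous) == (
                expected["entry"],
                expected["offset"],
                expected["strand"],
                expected["ambiguous"],
            )
            assert h.identity == pytest.approx(expected["identity"], abs=1e-12)


def test_edlib_mode_finds_indel_tolerant_hits(toy_panel):
    mono = toy_panel["satX"].sequence
    read = mono[20:50] + mono[51:81]  # one-base deletion
    strict = align_read(read, toy_panel, MapperConfig(min_identity=0.95))
    lenient = align_read(read, toy_panel, MapperConfig(min_identity=0.95, allow_indels=True))
    assert strict is None
    assert lenient is not None and lenient.entry == "satX"


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_identity_reported_only_above_threshold(seed):
    rng = np.random.default_rng(seed)
    panel = ReferencePanel([PanelEntry("s", random_seq(rng, 80), is_tandem=True)])
    read = mutate_seq(rng, panel["s"].target[5:45], rng.uniform(0, 0.5))
    hit = align_read(read, panel)
    if hit is not None:
        assert hit.identity >= 0.8
        assert 0 <= hit.monomer_offset < 80
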