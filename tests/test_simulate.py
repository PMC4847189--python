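"""Synthetic-data generator: determinism, tiling, sampling model, fibres."""

import dataclasses
import io

import numpy as np
import pytest

from satcen._seq import revcomp
from satcen.consensus import gc_content
from satcen.simulate import (
    MonomerSpec,
    SimConfig,
    SimTruth,
    alpha_for_ratio,
    build_panel,
    expected_ratios,
    parse_read_id,
    read_fastq,
    simulate_fibres,
    simulate_genome,
    simulate_reads,
    simulate_slot_blot,
    synthetic_monomer,
    write_fastq,
)


def _fastq_bytes(reads) -> bytes:
    buf = io.StringIO()
    for rid, seq in reads:
        buf.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return buf.getvalue().encode()


def test_same_seed_gives_byte_identical_outputs(small_cfg):
    g1, a1 = simulate_genome(small_cfg)
    g2, a2 = simulate_genome(small_cfg)
    assert g1 == g2
    assert a1.equals(a2)
    r1 = simulate_reads(g1, a1, small_cfg, "ip")
    r2 = simulate_reads(g2, a2, small_cfg, "ip")
    assert _fastq_bytes(r1) == _fastq_bytes(r2)
    f1, f2 = simulate_fibres(small_cfg), simulate_fibres(small_cfg)
    assert all(np.array_equal(p.green, q.green) for p, q in zip(f1, f2))
    assert simulate_genome(dataclasses.replace(small_cfg, seed=8))[0] != g1


def test_annotations_tile_genome_without_overlap(small_genome):
    genome, ann = small_genome
    assert ann.start.iloc[0] == 0
    assert ann.end.iloc[-1] == len(genome)
    assert (ann.start < ann.end).all()
    assert (ann.end.to_numpy()[:-1] == ann.start.to_numpy()[1:]).all()


def test_tandem_array_regions_are_exact_monomer_concatenations():
    cfg = SimConfig(
        seed=3,
        array_copies={"cen_sat": [10]},
        interspersed_copies={},
        occupancy={"cen_sat": 1.0},
        background_length=5_000,
        per_copy_mutation_rate=0.0,
        fibre_counts=(1, 1, 1),
    )
    genome, ann = simulate_genome(cfg)
    mono = build_panel(cfg)["cen_sat"].sequence
    region = ann[ann.family == "cen_sat"].iloc[0]
    assert region.end - region.start == 2210
    assert genome[region.start : region.end] == mono * 10


def test_zero_error_input_reads_are_exact_genome_substrings(small_cfg, small_genome):
    genome, ann = small_genome
    cfg = dataclasses.replace(small_cfg, substitution_error_rate=0.0)
    reads = simulate_reads(genome, ann, cfg, "input", n_reads=300)
    assert len(reads) == 300
    for rid, seq in reads:
        truth = parse_read_id(rid)
        sub = genome[truth["start"] : truth["start"] + cfg.read_length]
        assert seq == (sub if truth["strand"] == "+" else revcomp(sub))


def test_read_counts_are_exact_and_ids_encode_source(small_cfg, small_genome):
    genome, ann = small_genome
    reads = simulate_reads(genome, ann, small_cfg, "ip", n_reads=1234)
    assert len(reads) == 1234
    truth = parse_read_id(reads[0][0])
    assert truth["channel"] == "ip"
    assert ann.iloc[truth["region_id"]].family == truth["family"]


def test_input_family_fractions_match_genomic_length_fractions(small_cfg, small_genome):
    genome, ann = small_genome
    cfg = dataclasses.replace(small_cfg, substitution_error_rate=0.0)
    n = 50_000
    reads = simulate_reads(genome, ann, cfg, "input", n_reads=n)
    fams = [parse_read_id(r[0])["family"] for r in reads]
    lens = (ann.end - ann.start).groupby(ann.family).sum()
    for fam in ("cen_sat", "ere_like", "background"):
        p = lens[fam] / lens.sum()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(fams.count(fam) / n - p) < 3 * se


def test_alpha_zero_makes_ip_and_input_distributions_equal(small_cfg, small_genome):
    genome, ann = small_genome
    cfg = dataclasses.replace(small_cfg, ip_enrichment_alpha=0.0)
    assert expected_ratios(ann, 0.0)["cen_sat"] == pytest.approx(1.0)
    n = 30_000
    ip = [parse_read_id(r[0])["family"] for r in simulate_reads(genome, ann, cfg, "ip", n_reads=n)]
    p_cen = (ann.end - ann.start)[ann.family == "cen_sat"].sum() / len(genome)
    se = np.sqrt(p_cen * (1 - p_cen) / n)
    assert abs(ip.count("cen_sat") / n - p_cen) < 3 * se


def test_ip_enrichment_follows_closed_form_expectation(small_cfg, small_genome):
    """The estimated IP/input family ratio (from read truth labels) lands
    within 3 binomial SE of the two-state weight model's expectation."""
    genome, ann = small_genome
    truth = expected_ratios(ann, small_cfg.ip_enrichment_alpha)
    n = 60_000
    ip = [parse_read_id(r[0])["family"] for r in simulate_reads(genome, ann, small_cfg, "ip", n_reads=n)]
    inp = [parse_read_id(r[0])["family"] for r in simulate_reads(genome, ann, small_cfg, "input", n_reads=n)]
    x_ip, x_in = ip.count("cen_sat"), inp.count("cen_sat")
    est = (x_ip / n) / (x_in / n)
    rel_se = np.sqrt(1 / x_ip + 1 / x_in)
    assert abs(est - truth["cen_sat"]) < 3 * rel_se * truth["cen_sat"]


def test_alpha_for_ratio_inverts_expected_ratio(small_cfg):
    for target in (2.0, 6.5, 10.0):
        alpha = alpha_for_ratio(small_cfg, "cen_sat", target)
        _, ann = simulate_genome(small_cfg)
        assert expected_ratios(ann, alpha)["cen_sat"] == pytest.approx(target, rel=1e-9)
    with pytest.raises(ValueError, match="unattainable"):
        alpha_for_ratio(small_cfg, "cen_sat", 1e6)


def test_rna_reads_come_only_from_transcribed_regions(small_cfg, small_genome):
    genome, ann = small_genome
    reads = simulate_reads(genome, ann, small_cfg, "rna", n_reads=2_000)
    transcribed = set(ann[ann.expression > 0].region_id)
    assert {parse_read_id(r[0])["region_id"] for r in reads} <= transcribed


def test_empty_panel_and_oversized_reads_raise(small_cfg, small_genome):
    with pytest.raises(ValueError, match="empty panel"):
        SimConfig(monomers=[])
    genome, ann = small_genome
    bad = dataclasses.replace(small_cfg)
    object.__setattr__(bad, "read_length", len(genome) + 1)
    with pytest.raises(ValueError, match="read_length"):
        simulate_reads(genome, ann, bad, "input", n_reads=10)


def test_synthetic_monomer_hits_exact_gc(rng):
    for length, gc in ((221, 0.53), (137, 0.40), (100, 0.0), (100, 1.0)):
        seq = synthetic_monomer(length, gc, rng)
        assert len(seq) == length
        assert gc_content(seq) == pytest.approx(100 * round(gc * length) / length)


def test_fibre_profiles_counts_channels_and_truth_classes(small_cfg):
    profiles = simulate_fibres(small_cfg)
    assert len(profiles) == sum(small_cfg.fibre_counts)
    assert [p.true_class for p in profiles].count("I") == small_cfg.fibre_counts[0]
    for p in profiles:
        assert len(p.red) == len(p.green) == len(p.positions)
        assert (p.red >= 0).all() and (p.green >= 0).all()
    # pattern III fibres carry no green blocks in truth
    assert all(not p.true_green_blocks for p in profiles if p.true_class == "III")


def test_fastq_roundtrip_and_malformed_record_detection(tmp_path, small_cfg, small_genome):
    genome, ann = small_genome
    reads = simulate_reads(genome, ann, small_cfg, "input", n_reads=50)
    path = tmp_path / "r.fastq"
    write_fastq(reads, path)
    assert list(read_fastq(path)) == [(r[0], r[1]) for r in reads]
    corrupt = tmp_path / "bad.fastq"
    corrupt.write_text("@r0\nACGT\n+\nIIII\nr1 missing at\nACGT\n+\nIIII\n")
    with pytest.raises(ValueError, match="record at index 1"):
        list(read_fastq(corrupt))


def test_slot_blot_values_reflect_enrichment(small_cfg, small_genome):
    _, ann = small_genome
    truth = SimTruth.from_config(small_cfg, ann)
    df = simulate_slot_blot(small_cfg, truth)
    row = df.set_index("probe").loc["cen_sat"]
    assert row.idv_ip > row.idv_input  # enriched probe blots darker in IP
    unbound = df.set_index("probe").loc["ere_like"]
    assert unbound.idv_ip == pytest.approx(unbound.idv_input, rel=0.25)
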