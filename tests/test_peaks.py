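"""Stringent peak filtering and the window-based domain caller."""

import dataclasses

import numpy as np
import pytest

from satcen.peaks import (
    PeakFilterCriteria,
    PeakRecord,
    _bh_neg_log10,
    call_domains,
    coverage_track,
    filter_peaks,
    read_peak_table,
    write_peak_table,
)
from satcen.simulate import parse_read_id, simulate_reads
from satcen.tandem import classify_region


def _record(fe, pileup, p, q, start=0):
    return PeakRecord("contig1", start, start + 100, fe, pileup, p, q)


def test_strict_thresholds_boundary_behaviour():
    criteria = PeakFilterCriteria()
    kept, summary = filter_peaks(
        [_record(6, 150, 120, 110), _record(5, 150, 120, 110, start=200)], criteria
    )
    assert len(kept) == 1 and kept[0].start == 0  # FE exactly 5 fails (strict)
    assert summary == {"total": 2, "kept": 1, "dropped": 1}


@pytest.mark.parametrize("field", ["fold_enrichment", "pileup", "neg_log10_p", "neg_log10_q"])
def test_each_statistic_is_enforced(field):
    good = {"fold_enrichment": 6.0, "pileup": 150.0, "neg_log10_p": 120.0, "neg_log10_q": 110.0}
    bad = dict(good)
    bad[field] = 40.0 if field != "fold_enrichment" else 4.0
    rec = PeakRecord("c", 0, 10, **bad)
    kept, _ = filter_peaks([rec])
    assert kept == []


def test_filter_matches_bruteforce_scan_on_random_records(rng):
    records = [
        _record(
            float(rng.uniform(0, 10)),
            float(rng.uniform(0, 200)),
            float(rng.uniform(0, 200)),
            float(rng.uniform(0, 200)),
            start=i * 10,
        )
        for i in range(1000)
    ]
    criteria = PeakFilterCriteria()
    kept, _ = filter_peaks(records, criteria)
    brute = [
        r
        for r in records
        if r.fold_enrichment > 5 and r.pileup > 100 and r.neg_log10_p > 100 and r.neg_log10_q > 100
    ]
    assert kept == brute


def test_filter_monotone_under_threshold_relaxation(rng):
    records = [
        _record(
            float(rng.uniform(0, 10)),
            float(rng.uniform(0, 200)),
            float(rng.uniform(0, 200)),
            float(rng.uniform(0, 200)),
            start=i * 10,
        )
        for i in range(400)
    ]
    base = PeakFilterCriteria()
    n_base = len(filter_peaks(records, base)[0])
    for field in ("min_fold_enrichment", "min_pileup", "min_neg_log10_p", "min_neg_log10_q"):
        relaxed = dataclasses.replace(base, **{field: getattr(base, field) / 2})
        assert len(filter_peaks(records, relaxed)[0]) >= n_base


def test_filter_is_idempotent(rng):
    records = [
        _record(float(rng.uniform(0, 10)), 150, 120, 110, start=i * 10) for i in range(100)
    ]
    once, _ = filter_peaks(records)
    twice, _ = filter_peaks(once)
    assert once == twice


def test_peak_table_roundtrip_and_malformed_row(tmp_path):
    records = [_record(6, 150, 120, 110), _record(8, 170, 130, 120, start=300)]
    path = tmp_path / "peaks.tsv"
    write_peak_table(records, path)
    assert read_peak_table(path) == records

    bad = tmp_path / "bad.tsv"
    bad.write_text(
        "chrom\tstart\tend\tfold_enrichment\tpileup\tneg_log10_p\tneg_log10_q\n"
        "c1\t0\t100\t6\t150\t120\t110\n"
        "c1\t0\t100\tsix\t150\t120\t110\n"
    )
    with pytest.raises(ValueError, match="line 3"):
        read_peak_table(bad)


def test_peak_table_case_insensitive_macs_style_headers(tmp_path):
    path = tmp_path / "macs.tsv"
    path.write_text(
        "Chr\tStart\tEnd\tPileup\t-log10(pvalue)\tFold_enrichment\t-log10(qvalue)\n"
        "contig7\t10\t900\t220\t150\t7.5\t140\n"
    )
    (rec,) = read_peak_table(path)
    assert rec.contig == "contig7"
    assert rec.fold_enrichment == 7.5
    assert rec.neg_log10_q == 140


def test_bh_qvalues_monotone_and_bounded(rng):
    neg_p = rng.uniform(0, 300, size=50)
    neg_q = _bh_neg_log10(neg_p)
    order = np.argsort(-neg_p)  # increasing p
    q_sorted = neg_q[order]
    assert (np.diff(-q_sorted) >= -1e-9).all()  # q nondecreasing with p rank
    assert (neg_q <= neg_p + 1e-9).all()  # q >= p always


def test_flat_equal_tracks_yield_no_domains():
    track = np.full(10_000, 5.0)
    assert call_domains(track, track) == []
    with pytest.raises(ValueError, match="cannot form ratio"):
        call_domains(track, np.zeros_like(track))


def test_called_domain_overlaps_true_enriched_array(small_cfg, small_genome):
    """With CENP-A occupancy confined to one family, the caller recovers
    domains overlapping the true arrays, which classify to that family."""
    genome, ann = small_genome
    cfg = dataclasses.replace(small_cfg, n_reads_ip=60_000, n_reads_input=60_000)
    tracks = {}
    for channel in ("ip", "input"):
        reads = simulate_reads(genome, ann, cfg, channel)
        starts = np.array([parse_read_id(r[0])["start"] for r in reads])
        tracks[channel] = coverage_track(starts, cfg.read_length, len(genome))
    domains = call_domains(tracks["ip"], tracks["input"], window=100, min_ratio=2.0)
    assert domains, "no domains called over the enriched arrays"
    arrays = ann[(ann.family == "cen_sat") & (ann.kind == "tandem_array")]
    from satcen.simulate import build_panel

    panel = build_panel(cfg)
    for d in domains:
        overlap = ((arrays.start < d.end) & (arrays.end > d.start)).any()
        assert overlap
        rc = classify_region(genome[d.start : d.end], panel)
        assert rc.family == "cen_sat"
    # every true array is hit by some domain
    for row in arrays.itertuples():
        assert any(d.start < row.end and d.end > row.start for d in domains)


def test_record_validation():
    with pytest.raises(ValueError, match="start must be < end"):
        PeakRecord("c", 10, 10, 1, 1, 1, 1)
    with pytest.raises(ValueError, match=">= 0"):
        PeakRecord("c", 0, 10, -1, 1, 1, 1)
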