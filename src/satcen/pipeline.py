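"""End-to-end orchestration: simulate → map → enrich → consensus →
classify → filter → quantify, with a reproducibility manifest.

Every stage writes plain-text tables; re-running with the same config and
seed reproduces all non-image outputs byte-identically (the manifest
records a SHA-256 checksum per output so this is checkable).  The domain
caller consumes coverage tracks built from the simulated reads' true
source positions — the synthetic stand-in for the genome-alignment step
that is outside this package's scope.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from satcen import __version__
from satcen.consensus import build_matrix, consensus_call, gc_content
from satcen.enrichment import EnrichmentTable, RnaWindowPanel, count_rna_windows
from satcen.fibres import classify_fibre, segment_profile, slot_table, summarize_fibres, SlotBlotMeasurement
from satcen.mapping import MapperConfig, ReadMapper, write_hits_tsv
from satcen.peaks import (
    PeakFilterCriteria,
    call_domains,
    coverage_track,
    filter_peaks,
    peaks_to_frame,
    tally_by_family,
    write_peak_table,
)
from satcen.simulate import (
    SimConfig,
    SimTruth,
    build_panel,
    parse_read_id,
    simulate_fibres,
    simulate_genome,
    simulate_reads,
    simulate_slot_blot,
    write_fastq,
)
from satcen.tandem import classify_region

log = logging.getLogger("satcen")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    cfg: SimConfig,
    out_dir: str | Path,
    mapper_config: MapperConfig | None = None,
    criteria: PeakFilterCriteria | None = None,
    make_figures: bool = True,
) -> dict:
    """Run the full synthetic analysis; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mapper_config = mapper_config or MapperConfig()
    criteria = criteria or PeakFilterCriteria()
    t0 = time.time()
    manifest: dict = {
        "tool": "satcen",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "mapper": dataclasses.asdict(mapper_config),
        "peak_criteria": dataclasses.asdict(criteria),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {},
    }

    def register(path: Path) -> None:
        manifest["outputs"][path.name] = _sha256(path)

    # ---------------------------------------------------------- simulate
    log.info("[simulate] building genome and read sets (seed=%d)", cfg.seed)
    genome, annotations = simulate_genome(cfg)
    panel = build_panel(cfg)
    truth = SimTruth.from_config(cfg, annotations)
    with open(out / "genome.fa", "w") as fh:
        fh.write(">chrS synthetic satellite genome\n")
        for i in range(0, len(genome), 80):
            fh.write(genome[i : i + 80] + "\n")
    annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    panel.to_fasta(out / "panel.fa")
    truth.to_json(out / "truth.json")
    read_sets = {}
    for channel in ("ip", "input", "rna"):
        reads = simulate_reads(genome, annotations, cfg, channel)
        read_sets[channel] = reads
        write_fastq(reads, out / f"reads_{channel}.fastq")
        register(out / f"reads_{channel}.fastq")
    for name in ("genome.fa", "annotations.tsv", "panel.fa", "truth.json"):
        register(out / name)

    # --------------------------------------------------------------- map
    log.info("[map] aligning IP and input reads to the consensus panel")
    mapper = ReadMapper(panel, mapper_config)
    hits, summaries = {}, {}
    for channel in ("ip", "input"):
        hits[channel], summaries[channel] = mapper.map_reads(read_sets[channel])
        write_hits_tsv(hits[channel], out / f"hits_{channel}.tsv")
        register(out / f"hits_{channel}.tsv")

    # ------------------------------------------------------------ enrich
    log.info("[enrich] computing normalized IP/input ratios")
    table = EnrichmentTable.from_summaries(summaries["ip"], summaries["input"], panel)
    table.to_tsv(out / "enrichment.tsv")
    register(out / "enrichment.tsv")

    # --------------------------------------------------------- consensus
    ratios = table.frame.set_index("entry").ratio.fillna(0.0)
    cen = max((e for e in panel if e.is_tandem), key=lambda e: ratios[e.name])
    log.info("[consensus] building base-frequency matrix for %s", cen.name)
    cen_hits = [h for h in hits["ip"] if h.entry == cen.name]
    matrix = build_matrix(cen_hits, dict(read_sets["ip"]), cen.monomer_length)
    matrix.to_tsv(out / "matrix.tsv")
    consensus = consensus_call(matrix)
    with open(out / "consensus.fa", "w") as fh:
        fh.write(f">{cen.name}_consensus\n{consensus}\n")
    register(out / "matrix.tsv")
    register(out / "consensus.fa")

    # --------------------------------------------------------------- rna
    log.info("[rna] counting satellite vs gene transcription windows")
    gene_windows = []
    for gene in cfg.genes:
        row = annotations[(annotations.family == gene.name) & (annotations.kind == "gene")].iloc[0]
        gene_windows.append((gene.name, genome[row.start : row.end]))
    rna_panel = RnaWindowPanel.build(gene_windows, satellites=[cen])
    rna_counts = count_rna_windows(read_sets["rna"], rna_panel, mapper_config)
    rna_counts.to_csv(out / "rna_counts.tsv", sep="\t", index=False)
    register(out / "rna_counts.tsv")

    # ------------------------------------------------------------- peaks
    log.info("[peaks] calling and filtering enrichment domains")
    m = cfg.read_length
    tracks = {}
    for channel in ("ip", "input"):
        starts = np.array([parse_read_id(rid)["start"] for rid, _ in read_sets[channel]])
        tracks[channel] = coverage_track(starts, m, len(genome))
    domains = call_domains(tracks["ip"], tracks["input"], read_length=m)
    write_peak_table(domains, out / "peaks_raw.tsv")
    kept, peak_summary = filter_peaks(domains, criteria)
    write_peak_table(kept, out / "peaks_filtered.tsv")
    classifications = {}
    class_rows = []
    for p in kept:
        rc = classify_region(genome[p.start : p.end], panel, mapper_config, region_id=f"{p.contig}:{p.start}-{p.end}")
        classifications[(p.contig, p.start, p.end)] = rc.family
        class_rows.append(
            (rc.region_id, rc.family or "unclassified", rc.mean_identity, rc.head_to_tail, rc.period)
        )
    pd.DataFrame(
        class_rows, columns=["region", "family", "mean_identity", "head_to_tail", "period"]
    ).to_csv(out / "classifications.tsv", sep="\t", index=False)
    peak_summary["per_family"] = tally_by_family(kept, classifications)
    register(out / "peaks_raw.tsv")
    register(out / "peaks_filtered.tsv")
    register(out / "classifications.tsv")

    # ------------------------------------------------------------ fibres
    log.info("[fibres] simulating and classifying chromatin fibres")
    profiles = [segment_profile(p) for p in simulate_fibres(cfg)]
    classes = [classify_fibre(p) for p in profiles]
    fibre_frame = pd.DataFrame(
        {
            "fibre": [p.fibre_id for p in profiles],
            "true_class": [p.true_class for p in profiles],
            "called_class": classes,
            "coverage_fraction": [p.coverage_fraction for p in profiles],
            "n_green_blocks": [len(p.green_blocks) for p in profiles],
        }
    )
    fibre_frame.to_csv(out / "fibre_classes.tsv", sep="\t", index=False)
    fibre_summary = summarize_fibres(classes)
    fibre_summary.to_csv(out / "fibre_summary.tsv", sep="\t", index=False)
    traces_dir = out / "fibre_traces"
    traces_dir.mkdir(exist_ok=True)
    for p in profiles:
        p.to_tsv(traces_dir / f"{p.fibre_id}.tsv")
    register(out / "fibre_classes.tsv")
    register(out / "fibre_summary.tsv")

    # --------------------------------------------------------- slot blot
    slots = simulate_slot_blot(cfg, truth)
    slots.to_csv(out / "slot_blot.tsv", sep="\t", index=False)
    measurements = [
        SlotBlotMeasurement(r.probe, r.idv_ip, r.idv_input, r.background) for r in slots.itertuples()
    ]
    slot_frame = slot_table(measurements)
    slot_frame.to_csv(out / "slot_ratios.tsv", sep="\t", index=False)
    register(out / "slot_blot.tsv")
    register(out / "slot_ratios.tsv")

    # ----------------------------------------------------------- figures
    if make_figures:
        from satcen import report

        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        report.plot_enrichment(table, figdir / "enrichment.png")
        report.plot_logo(matrix, figdir / "logo.png")
        report.plot_rna_counts(rna_counts, figdir / "rna_counts.png")
        for p in profiles[:6]:
            report.plot_fibre(p, figdir / f"{p.fibre_id}.png")

    # ----------------------------------------------------------- summary
    summary = {
        "seed": cfg.seed,
        "expected_ratios": truth.expected_ratios,
        "estimated_ratios": {
            r.entry: (None if bool(r.undefined) else float(r.ratio)) for r in table.frame.itertuples()
        },
        "consensus_gc_percent": gc_content(consensus),
        "consensus_matches_monomer": consensus == cen.sequence,
        "peaks": peak_summary,
        "fibres": {row.pattern: int(row.count) for row in fibre_summary.itertuples()},
        "fibre_percentages": {row.pattern: int(row.percent) for row in fibre_summary.itertuples()},
        "slot_ratios": {r.probe: (None if r.undefined else float(r.ratio)) for r in slot_frame.itertuples()},
        "mapping": {
            ch: {
                "total": summaries[ch].total_reads,
                "mapped": summaries[ch].mapped,
                "ambiguous": summaries[ch].ambiguous,
                "per_entry": summaries[ch].per_entry,
            }
            for ch in ("ip", "input")
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    register(out / "summary.json")

    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("[done] pipeline finished in %.1fs → %s", manifest["elapsed_seconds"], out)
    return manifest
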