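"""End-to-end runs tying the stages into the two workflows.

``run_pipeline`` executes, from one seeded configuration: simulation of the
study region and pooled counts, the sex scan, expected-Y construction,
long-read classification, and consensus over the Y-specific subset. It
writes every intermediate in its standard format plus a machine-readable
JSON report; the whole run is reproducible byte-for-byte from
(preset, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import consensus as cns
from . import io, longread, poolscan, presets, sim, yhap

logger = logging.getLogger(__name__)


@dataclass
class PipelineReport:
    preset: str
    seed: int
    n_sites: int
    n_windows: int
    top_window: dict | None
    n_enriched_windows: int
    n_reads: int
    n_bait_pass: int
    label_counts: dict
    consensus_length: int
    consensus_ambiguous: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def run_pipeline(
    preset_name: str,
    seed: int,
    outdir: str | Path,
    scan_config: poolscan.ScanConfig | None = None,
) -> PipelineReport:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    preset = presets.get_preset(preset_name)
    rng = np.random.default_rng(seed)
    s_ref, s_pool, s_reads = (int(rng.integers(2**31)) for _ in range(3))

    # --- reference + haplotypes ------------------------------------------
    x_seq, genes = presets.build_study_region(seed=s_ref)
    io.write_fasta([("chrX_region", x_seq)], outdir / "x_haplotype.fasta")
    io.write_bed(genes, outdir / "annotations.bed")

    # The expected Y is prior knowledge (breakpoints from earlier short-read
    # work), so it is constructed for every preset; whether the simulated
    # individual actually carries the duplication is a separate question.
    spec = presets.default_yspec(
        x_seq, with_exon6_insertion=preset.with_exon6_insertion
    )
    io.write_spec(spec, outdir / "y_variants.yaml")
    model = yhap.build_expected_y(x_seq, genes, spec)
    io.write_fasta([("expected_Y", model.y_sequence)], outdir / "expected_y.fasta")
    true_y = None
    if preset.has_duplication:
        true_y, _ = sim.make_true_y(x_seq, spec)

    # --- pooled scan ------------------------------------------------------
    pool_cfg = replace(preset.pool, seed=s_pool)
    sites, pool_truth = sim.simulate_pool_counts(
        x_seq, spec if pool_cfg.sex_system == "XY" else None, pool_cfg
    )
    io.write_sync(sites, outdir / "pools.sync")
    scan_cfg = scan_config or poolscan.ScanConfig()
    result = poolscan.scan(sites, scan_cfg)
    result.records.to_csv(outdir / "scan_records.tsv", sep="\t", index=False)
    result.windows.to_csv(outdir / "scan_windows.tsv", sep="\t", index=False)
    enriched = poolscan.enriched_windows(result.windows)
    top = None
    if not result.windows.empty:
        top_row = result.windows.sort_values(
            ["n_candidates", "window_start"], ascending=[False, True]
        ).iloc[0]
        top = {
            "window_start": int(top_row.window_start),
            "window_end": int(top_row.window_end),
            "n_candidates": int(top_row.n_candidates),
        }

    # --- long reads -------------------------------------------------------
    err = replace(preset.error_model, seed=s_reads)
    reads, read_truth = sim.simulate_read_set(
        x_seq, true_y, preset.n_long_reads, preset.y_read_fraction, err
    )
    io.write_fastq(
        [(rid, seq, sim.constant_quality(seq, err.error_rate)) for rid, seq in reads],
        outdir / "long_reads.fastq",
    )

    cons_len = cons_amb = 0
    baits = longread.prepare_baits(genes, x_seq)
    cls = longread.classify_reads(reads, model, baits)
    n_bait = cls.n_bait_pass
    label_counts = dict(cls.label_counts())
    _write_calls(cls, reads, outdir)
    y_ids = set(cls.subset(longread.LABEL_Y))
    y_reads = [(rid, longread.trim_ends(seq) or "")
               for rid, seq in reads if rid in y_ids]
    if y_reads:
        mat = cns.stack_alignments(y_reads, model.y_sequence)
        res = cns.call_consensus(mat)
        cons_len, cons_amb = len(res.sequence), res.n_ambiguous
        io.write_fasta([("y_consensus", res.sequence)],
                       outdir / "y_consensus.fasta")

    report = PipelineReport(
        preset=preset_name,
        seed=seed,
        n_sites=len(result.records),
        n_windows=len(result.windows),
        top_window=top,
        n_enriched_windows=len(enriched),
        n_reads=len(reads),
        n_bait_pass=n_bait,
        label_counts=label_counts,
        consensus_length=cons_len,
        consensus_ambiguous=cons_amb,
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _write_calls(cls: longread.ClassificationResult, reads, outdir: Path) -> None:
    with open(outdir / "read_calls.tsv", "w") as fh:
        fh.write("read_id\tbait_hit\tlabel\tspans_locus\tdeletion_detected\t"
                 "observed_length\n")
        for c in cls.calls:
            fh.write(
                f"{c.read_id}\t{c.bait_hit or '.'}\t{c.label}\t"
                f"{int(c.diagnostic.spans_locus)}\t"
                f"{int(c.diagnostic.deletion_detected)}\t"
                f"{c.diagnostic.observed_length if c.diagnostic.observed_length is not None else '.'}\n"
            )
    by_label: dict[str, list] = {}
    seq_of = dict(reads)
    for c in cls.calls:
        by_label.setdefault(c.label, []).append((c.read_id, seq_of[c.read_id]))
    for label, recs in by_label.items():
        safe = label.replace("-", "_").lower()
        io.write_fasta(recs, outdir / f"reads_{safe}.fasta")
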