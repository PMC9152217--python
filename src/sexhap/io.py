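"""File formats: Popoolation2 sync, FASTA/FASTQ, BED, and the variant spec.

FASTA/FASTQ go through Biopython; the sync dialect (one tab-separated
``A:T:C:G:N:del`` count column per pool) is written and parsed here since no
installed library reads it. Malformed sync lines are skipped and tallied,
never fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .poolscan import PooledSiteCounts
from .sim import Deletion, GeneModel, YVariantSpec

logger = logging.getLogger(__name__)

SYNC_ORDER = ("A", "T", "C", "G", "N", "del")


@dataclass
class SyncReadResult:
    sites: list[PooledSiteCounts]
    n_malformed: int = 0


def _parse_pool(field_: str) -> dict[str, int]:
    parts = field_.split(":")
    if len(parts) != 6:
        raise ValueError(f"expected 6 colon-separated counts, got {field_!r}")
    return {b: int(c) for b, c in zip(SYNC_ORDER, parts)}


def read_sync(path: str | Path, swap_pools: bool = False) -> SyncReadResult:
    """Parse a two-pool sync file; pool1 = first count column unless
    ``swap_pools``."""
    sites: list[PooledSiteCounts] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) != 5:
                    raise ValueError(f"expected 5 tab-separated fields, got {len(fields)}")
                chrom, pos, ref = fields[0], int(fields[1]), fields[2]
                p1, p2 = _parse_pool(fields[3]), _parse_pool(fields[4])
                if swap_pools:
                    p1, p2 = p2, p1
                sites.append(PooledSiteCounts(chrom, pos, ref, p1, p2))
            except (ValueError, IndexError) as exc:
                n_bad += 1
                logger.warning("sync line %d skipped: %s", lineno, exc)
    return SyncReadResult(sites=sites, n_malformed=n_bad)


def write_sync(sites, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            cols = [
                ":".join(str(counts.get(b, 0)) for b in SYNC_ORDER)
                for counts in (s.pool1_counts, s.pool2_counts)
            ]
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{cols[0]}\t{cols[1]}\n")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; qualities are parsed but not carried."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def write_fastq(records: list[tuple[str, str, str]], path: str | Path) -> None:
    """records are (id, sequence, quality-string) triples."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_bed(genes: list[GeneModel], path: str | Path, chrom: str = "chr1") -> None:
    """Gene spans as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            s, e = g.span
            fh.write(f"{chrom}\t{s - 1}\t{e}\t{g.name}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# variant spec + gene models (YAML)
# ---------------------------------------------------------------------------

def spec_to_dict(spec: YVariantSpec) -> dict:
    d = {
        "dup_source": list(spec.dup_source),
        "dup_insert_at": spec.dup_insert_at,
        "deletions": [
            {"start": x.start, "end": x.end, **({"override": x.override} if x.override else {})}
            for x in spec.deletions
        ],
        "insertions": [[p, s] for p, s in spec.insertions],
        "snvs": [[p, b] for p, b in spec.snvs],
    }
    if spec.diagnostic_deletion is not None:
        d["diagnostic_deletion"] = {
            "start": spec.diagnostic_deletion.start,
            "end": spec.diagnostic_deletion.end,
            "expected_length": spec.diagnostic_expected_length,
        }
    return d


def spec_from_dict(d: dict) -> YVariantSpec:
    known = {"dup_source", "dup_insert_at", "deletions", "insertions", "snvs",
             "diagnostic_deletion"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown spec keys: {sorted(unknown)}")
    diag = d.get("diagnostic_deletion")
    return YVariantSpec(
        dup_source=tuple(d["dup_source"]),
        dup_insert_at=int(d["dup_insert_at"]),
        deletions=[Deletion(x["start"], x["end"], x.get("override")) for x in
                   d.get("deletions", [])],
        insertions=[(int(p), str(s)) for p, s in d.get("insertions", [])],
        snvs=[(int(p), str(b)) for p, b in d.get("snvs", [])],
        diagnostic_deletion=(
            Deletion(diag["start"], diag["end"]) if diag else None
        ),
        diagnostic_expected_length=(
            int(diag.get("expected_length", 275)) if diag else 275
        ),
    )


def read_spec(path: str | Path) -> YVariantSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def write_spec(spec: YVariantSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def genes_to_dicts(genes: list[GeneModel]) -> list[dict]:
    return [
        {
            "name": g.name,
            "exons": [list(e) for e in g.exons],
            "strand": g.strand,
            "masked_intervals": [list(m) for m in g.masked_intervals],
        }
        for g in genes
    ]


def genes_from_dicts(items: list[dict]) -> list[GeneModel]:
    return [
        GeneModel(
            name=d["name"],
            exons=[tuple(e) for e in d["exons"]],
            strand=d.get("strand", "+"),
            masked_intervals=[tuple(m) for m in d.get("masked_intervals", [])],
        )
        for d in items
    ]
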