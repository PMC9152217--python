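#!/usr/bin/env python
"""Step 4 — bait-filter and classify the long reads.

For each scenario, reads are kept when they share sequence with the focal
genes, trimmed, and labelled by evidence at the 275 bp diagnostic deletion:
Y-specific (deletion present), non-Y (locus spanned, no deletion) or
unassigned. The null scenario must produce zero Y-specific reads.
"""

import argparse
import subprocess
import sys
from pathlib import Path

PRESETS = ("kpandu-like", "koka-like", "hora-like")


def run(outroot: Path) -> None:
    for preset in PRESETS:
        indir = outroot / preset
        out = indir / "classify"
        proc = subprocess.run(
            [sys.executable, "-m", "sexhap.cli", "classify",
             "--reads", str(indir / "long_reads.fastq"),
             "--x", str(indir / "x_haplotype.fasta"),
             "--spec", str(indir / "y_variants.yaml"),
             "--out", str(out)],
            check=True, capture_output=True, text=True,
        )
        print(f"{preset}: {proc.stdout.strip()}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outroot", type=Path, default=Path("results/analysis"))
    run(ap.parse_args().outroot)
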