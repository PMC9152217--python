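#!/usr/bin/env python
"""Step 5 — backbone consensus over the Y-specific reads.

Stacks each scenario's Y-specific reads (if any) on its expected-Y backbone
and calls a column-wise consensus with IUPAC ambiguity codes, then reports
how well the consensus matches the backbone over well-covered columns — the
final check that the reconstructed Y-specific region is internally
consistent.
"""

import argparse
import subprocess
import sys
from pathlib import Path

import pandas as pd

PRESETS = ("kpandu-like", "koka-like", "hora-like")


def run(outroot: Path) -> None:
    for preset in PRESETS:
        indir = outroot / preset
        y_reads = indir / "classify" / "reads_y_specific.fasta"
        if not y_reads.exists():
            print(f"{preset}: no Y-specific reads; consensus skipped")
            continue
        out = indir / "consensus"
        subprocess.run(
            [sys.executable, "-m", "sexhap.cli", "consensus",
             "--reads", str(y_reads),
             "--backbone", str(indir / "expected_y" / "expected_y.fasta"),
             "--out", str(out)],
            check=True,
        )
        cols = pd.read_csv(out / "consensus_columns.tsv", sep="\t")
        deep = cols[cols.depth >= 3]
        if len(deep):
            print(
                f"{preset}: consensus spans backbone "
                f"{int(cols.backbone_pos.min())}-{int(cols.backbone_pos.max())}; "
                f"{len(deep)} columns at depth>=3, "
                f"mean agreement {deep.agreement.mean():.3f}"
            )


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outroot", type=Path, default=Path("results/analysis"))
    run(ap.parse_args().outroot)
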