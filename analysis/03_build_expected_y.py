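#!/usr/bin/env python
"""Step 3 — construct the expected Y haplotype.

Builds the reference-guided Y model from each scenario's X haplotype and
variant spec, writes the expected-Y FASTA plus the per-base coordinate map,
and prints the length bookkeeping and the lifted annotations (duplicate
copies, truncations, the dot1l-oaz1 chimera).
"""

import argparse
import subprocess
import sys
from pathlib import Path

from sexhap import io, yhap
from sexhap.presets import default_genes

PRESETS = ("kpandu-like", "koka-like", "hora-like")


def run(outroot: Path) -> None:
    for preset in PRESETS:
        indir = outroot / preset
        out = indir / "expected_y"
        subprocess.run(
            [sys.executable, "-m", "sexhap.cli", "build-y",
             "--x", str(indir / "x_haplotype.fasta"),
             "--spec", str(indir / "y_variants.yaml"),
             "--out", str(out)],
            check=True,
        )
        # liftover report (library-level; the CLI writes sequence + map)
        x_seq = io.read_fasta(indir / "x_haplotype.fasta")[0][1]
        spec = io.read_spec(indir / "y_variants.yaml")
        model = yhap.build_expected_y(x_seq, default_genes(), spec)
        feats = yhap.liftover_annotations(model)
        print(f"{preset}: duplicated span {model.duplicated_span()} bp")
        for f in feats:
            if f.copy != "original":
                flag = " (truncated)" if f.truncated else ""
                print(f"  {f.name}: Y {f.start}-{f.end} [{f.copy}]{flag}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outroot", type=Path, default=Path("results/analysis"))
    run(ap.parse_args().outroot)
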