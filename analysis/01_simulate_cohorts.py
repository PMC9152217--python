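#!/usr/bin/env python
"""Step 1 — simulate the three study scenarios.

Generates, for each preset (two duplication carriers and one null), the X
haplotype, the Y structural-variant spec, pooled male/female allele counts
(sync) and a mixed long-read set, all under results/analysis/<preset>/.
Everything downstream reads these files; nothing re-simulates.
"""

import argparse
import subprocess
import sys
from pathlib import Path

PRESETS = ("kpandu-like", "koka-like", "hora-like")


def run(seed: int, outroot: Path) -> None:
    for i, preset in enumerate(PRESETS):
        out = outroot / preset
        subprocess.run(
            [sys.executable, "-m", "sexhap.cli", "simulate",
             "--preset", preset, "--seed", str(seed + i),
             "--outdir", str(out)],
            check=True,
        )


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--outroot", type=Path, default=Path("results/analysis"))
    a = ap.parse_args()
    run(a.seed, a.outroot)
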