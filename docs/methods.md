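# Methods

This document describes the model behind `sexhap`, the default parameters
and why they were chosen, and what the synthetic generator does and does
not emulate. All user-facing coordinates are 1-based inclusive; BED output
is 0-based half-open.

## 1. The synthetic study region

The default model (`sexhap.presets`) is a 200 kb X haplotype at 42% GC
carrying four genes in order: `dot1l` (first intron masked for bait use,
standing in for an intron that resembles an unrelated gene), `oaz1` (minus
strand), `LOC100707471` and `amh` (seven exons). The region size is this
package's own choice: large enough that the 51 kb duplication occupies only
a quarter of the genome — so the pooled scan has genuine null background —
while the whole pipeline still runs in seconds.

The Y differs from the X by a structural-variant spec (`YVariantSpec`):

- a tandem duplication of X 3,001–54,000 (51 kb) inserted immediately
  after its source, covering all four genes;
- on the duplicated copy: a 7,501 bp deletion fusing the truncated `dot1l`
  and `oaz1` copies into a `dot1l-oaz1_chimera`; a 5,501 bp deletion
  truncating the `LOC100707471` copy; the **275 bp diagnostic deletion**
  in the truncated `oaz1` copy (X-projected interval 17,001–17,275); a
  233 bp deletion in `amh` exon 7 and a 5 bp insertion in exon 6 (the
  truncating `amhΔY`-style edits; the insertion is absent in the
  `koka-like` preset); a small 120 bp intergenic deletion; three marker
  SNVs.

`make_true_y` applies *every* edit and returns the actual Y with a
per-base coordinate map (origin X position and a provenance tag:
original / duplicate / novel insertion). `build_expected_y` applies the
reconstruction rule instead (§3). Nothing downstream reads the truth; the
tests do.

## 2. Pooled sex scan

**Sampling model** (`sim.simulate_pool_counts`). Polymorphic sites are
placed at `snp_density` (default 2/kb). Inside the duplicated interval
under an XY system, the female pool is fixed for the reference (2n X
chromosomes) and the male pool sits at frequency 0.5 (n X + n Y); all
other sites share one population frequency drawn uniformly on
[0.05, 0.95] and sampled binomially into each pool's 2n chromosomes.
Read counts are multinomial at Poisson depth (`depth_mean`, default 170)
thinned by `subsample_fraction` (default 0.2, i.e. ~34× per pool —
deliberately modelling a scan run on a modest subsample), with per-base
error 0.002 redistributed over the other three bases.

**Statistics** (`poolscan`). Per pool, alleles below `min_read_count` = 2
reads are dropped before frequencies are computed. The per-site Fst is the
classical π-based pooled estimator, Fst = (π_T − π_W)/π_T with
π = 1 − Σp², computed from the retained counts (π_T from the summed
pools); closed forms 0, 1/3 and 1 are unit-tested, plus a brute-force
oracle over random toys.

**Filter.** A site is a candidate when both pool depths lie in
[`min_depth`, `max_depth`] = [10, 100] and, in either direction, one
pool's major allele has frequency ≥ 0.9 while *that same allele* lies in
[0.3, 0.7] in the other pool. Sites fixed in both pools, or without the
polymorphic counterpart, are rejected with a tallied reason. The
thresholds follow the established fixed-vs-intermediate heuristic for
XY pool scans.

**Windows.** Candidates are counted in non-overlapping 10 kb windows
(window k covers positions k·w+1 … (k+1)·w). A window is *enriched* when
its candidate count reaches both the 95th percentile of window counts and
an absolute floor of 5 candidates; the floor prevents a null genome, where
the 95th percentile may be 1–2 sporadic false positives, from reporting
"enrichment".

## 3. Expected-Y construction

The expected Y is reference-guided: the X with the duplicated copy
inserted and the spec's edits applied by a size rule —

- deletions **< 500 bp are kept** in the model (long reads cross them;
  keeping the bases preserves anchors),
- deletions **≥ 5 kb are applied** (keeping them would badly distort
  coordinates),
- the **diagnostic deletion is always applied**, whatever its size,
- deletions between 500 bp and 5 kb are **refused** unless the spec marks
  them with an explicit per-deletion `override: apply|keep` — no general
  rule covers that range, and guessing silently would corrupt
  coordinates.

Every Y base keeps its provenance, giving three checked invariants:
|Y| = |X| + dup − applied deletions + insertions; dropping all
duplicate/insertion bases reproduces the X byte-for-byte; and the
duplicated span recovered from the map (duplicate-tagged bases + copy
bases removed by applied deletions) equals the spec's 51 kb exactly.
Annotation liftover emits original copies, `_dup` copies (flagged
`truncated` when an applied deletion removed part of them), and a single
`geneA-geneB_chimera` feature (upstream gene first) when one deletion
removes the tail of one copy and the head of the next.

## 4. Long-read model and classification

**Error model** (`LongReadErrorModel`). One total per-base error rate,
default 6.44%, split 40/30/30 between substitutions, insertions and
deletions; lognormal lengths with median 10 kb (σ = 0.35, minimum 1 kb).
Realigning simulated reads to their source recovers ~6.2–6.4% mean
per-base error; the small deficit versus the nominal rate is expected —
random errors occasionally cancel or re-match under an optimal alignment —
and lies well inside the ±0.3 point acceptance band.

**Bait filter.** Each gene contributes one bait segment per maximal
unmasked run of its span (a gene with one masked internal intron yields
two segments; a fully masked gene contributes nothing, with a warning).
Retention uses shared exact 15-mers between read and segment (both
strands), threshold 3 shared k-mers; an optional margin requires the best
gene to beat the runner-up, guarding against paralog-only matches. The
exact-k-mer score stands in for a local-alignment (BLAST-style) cutoff:
at 15 bp, chance hits in random sequence are essentially absent, and a
6.44%-error read still shares many exact 15-mers with a 600+ bp bait.
Reads then lose 23 bp at each end (low-quality tails).

**Diagnostic classification** (`classify_read`). The decisive design
choice: the deletion is *not* read off the gap runs of a read-to-X
alignment. Under unit edit costs a long deletion is routinely "smeared" —
the aligner prefers mismatching through deleted sequence (~0.5 cost/base
in expectation) over paying 1/base for a contiguous gap — so gap-run
lengths under-report structural deletions. Instead the two 200 bp X
flanks bordering the diagnostic interval are aligned *independently* into
the read (edlib infix mode, ≥ 70% identity each, same strand, coherent
order). The observed deletion is the anchors' separation on X (the 275 bp
interval itself) minus their separation on the read — a path-independent
readout. A read is **Y-specific** when both anchors place and the
separation deficit matches the expected 275 bp within ±30 bp; **non-Y**
when both anchors place without that deficit; **unassigned** otherwise
(including reads that end inside the locus: the far flank simply cannot
place). Error-free classification is exact; at 6.44% error, concordance
on locus-spanning reads exceeds 95% in the test suite.

**Alignment kernel.** All pairwise alignment is edlib (Myers bit-vector
edit distance with traceback) rather than a hand-rolled seeded
banded-affine aligner: it is exact for its cost model, deterministic and
very fast at these sizes. Its unit gap cost is precisely why structural
indel readout is anchor-based (above) and why the `amh`-copy indels are
measured as the *net* insertion-minus-deletion imbalance inside the
planted exon interval (`net_indel_in_target`) — the net is invariant to
how an optimal path distributes tied edits, so the 5 bp insertion and
233 bp deletion are recovered exactly.

## 5. Backbone consensus

Y-specific reads are aligned individually to the expected-Y backbone and
consensus is called per backbone column (star alignment — well-posed here
because a backbone exists by construction; no de-novo MSA). Columns below
depth 2 become `N`; gap-majority columns are deleted; a base is called at
≥ 60% agreement, otherwise the IUPAC code over bases with ≥ 25% support;
insertions relative to the backbone are emitted when at least half the
covering reads carry one, keyed to the column they follow. At the default
error rate, columns with depth ≥ 3 recover the template at ≥ 99%
identity (tested), and mean agreement in the worked example is 0.97.

## 6. What the generator does and does not emulate

Modelled: XY allele-frequency structure in pools, Poisson depth with
subsampling and per-base miscalls, lognormal long-read lengths with a
mixed substitution/indel error process, tandem duplication with nested
indels/SNVs and full provenance, read sets whose ids leak nothing about
origin (truth is returned separately).

Not modelled: diploid heterozygosity outside the sex-linked region within
individuals, linkage/recombination, mapping bias or reference-allele bias,
GC-dependent coverage, chimeric/split long reads, base-quality variation
along reads (qualities are emitted flat and unused), paralogous sequence
beyond the single masked intron stand-in, and multi-chromosome genomes.

## 7. Defaults at a glance

| parameter | default | rationale |
|---|---|---|
| region length | 200 kb | dup = ¼ of genome → real null background |
| duplication | X 3,001–54,000 (51 kb) | headline duplicated span |
| diagnostic deletion | 275 bp in `oaz1` copy | Y-read marker |
| pool size / depth | 10 per sex / Poisson 170 × 0.2 | ~34× after thinning |
| SNP density / error | 2 per kb / 0.002 | typical pool-seq scale |
| filter | 0.9 fixed, [0.3, 0.7] poly, depth [10, 100], min count 2 | standard XY heuristic |
| window / enrichment | 10 kb / q95 and ≥ 5 candidates | floor kills null "peaks" |
| deletion rule | keep < 500 bp, apply ≥ 5 kb, else explicit override | no silent guessing |
| long reads | 6.44% error (40/30/30), median 10 kb, 300 reads, ~50% Y | male-like mixture |
| bait k-mer | k = 15, ≥ 3 hits | negligible chance hits |
| trim | 23 bp per end | low-quality tails |
| classifier | 200 bp flanks, ≥ 0.7 identity, ±30 bp tolerance | anchors survive 6.44% error |
| consensus | depth ≥ 2, agreement 0.6, minor ≥ 0.25, insertion ≥ 0.5 | IUPAC at genuine ambiguity |

## 8. Limitations

- The scan's depth window [10, 100] interacts with Poisson depth: at mean
  depths near 100 many sites are discarded as too deep, which is faithful
  to the heuristic but costs power; the defaults (34× effective) sit
  comfortably inside the window.
- The diagnostic classifier reads evidence at a single locus; reads from
  the Y's *original* (non-duplicated) segment are correctly non-Y even
  though they physically came from the Y molecule. "Y-specific" means
  "carries the Y-diagnostic allele", not "sequenced from the Y".
- Consensus insertions are called from a side list keyed to one backbone
  column; insertions longer than a read's local accuracy can fragment.
- No affine gap costs anywhere; every structural readout is therefore
  anchor- or net-based by design (§4).
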