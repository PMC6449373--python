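# adrnmes

Neuroblastoma contains two interconvertible tumor cell states: lineage-committed
**adrenergic (ADRN)** cells and neural-crest-like **mesenchymal (MES)** cells, each
maintained by its own super-enhancer (SE) landscape and core regulatory circuitry
(CRC) of transcription factors. Activated NOTCH signaling (a NOTCH3 intracellular
domain, NOTCH3-IC) can reprogram ADRN cells to the MES state through a
transcriptional feed-forward cascade among NOTCH receptors, the ligand JAG1 and
the co-factor MAML2 — remodeling H3K27ac landscapes, flipping lineage SEs, and
becoming self-sustaining once induction has lasted long enough.

`adrnmes` is a tested, reusable implementation of the computational workflow
behind this kind of analysis, for computational biologists who want the bespoke
statistics as an importable library rather than one-off scripts:

* **Signature derivation** from isogenic MES/ADRN cell-line pairs: a gene joins a
  lineage signature when, in ≥ 3 pairs, it shows a per-pair fold change ≥ 2, a
  linear intensity difference ≥ 100, ≥ 1 Present detection call, and a consistent
  direction of regulation.
* **Rank-percentile signature scoring**: within a sample, all *N* probesets are
  rank-ordered (average ranks on ties); gene *g* gets percentile
  *p(g) = rank(g)/N*, and the score is the mean percentile over the signature —
  a single number per sample, invariant under any monotone transform of the
  intensities. A summed z-score variant (Σ per-gene *z*) is included for
  time-course figures.
* **Super-enhancer landscapes**: reads-per-20-million normalization of binned
  H3K27ac coverage, threshold peak calling, stitching within 12.5 kb, and the
  hockey-stick elbow cutoff — on min–max rescaled rank/signal axes, scanning from
  the top, SEs are the regions above the point where the discrete slope falls
  to 1.
* **Differential remodeling**: the *directional surface* of a region,
  `surface = bin_width × Σ_bins (B − A)` on normalized tracks, with a
  Poisson-noise filter, classifies lineage SEs as increased or decreased and
  ranks induced regions.
* **Motif enrichment**: JASPAR PWMs, log-odds scanning of both strands at a
  scale-free threshold (fraction of the maximum achievable score), one-sided
  Fisher's exact test of foreground vs background region hits with Bonferroni
  correction.
* **Cascade dynamics**: endogenous-vs-transgene decomposition via 3′UTR/CDS
  probesets (the transgene lacks the 3′UTR), per-TF regulation calls
  (|log2FC| ≥ 1), onset times (first persistent departure from baseline in
  within-gene sd units), and scenario verdicts (transitioned / blocked /
  reverted) from score trajectories.
* **A synthetic-data generator** that emulates the study designs — four isogenic
  pairs plus a cell-line panel, a 0/1/7/14/21-day induction time course with
  washout, inhibitor and transient scenarios and a commitment rule, and paired
  H3K27ac tracks with planted SEs and planted RBPJ-consensus motifs — together
  with the ground truth needed to test every stage.

## Worked example

```bash
python examples/01_signature_scoring.py
```

```
derived 293 MES and 238 ADRN genes
precision 1.000  recall 0.965 against planted truth

             mes_score  adrn_score lineage
pair1_MES        0.965       0.460     MES
pair1_ADRN       0.478       0.970    ADRN
...
```

The derivation recovers the planted signature genes essentially perfectly
(precision 1.0, recall 0.97), and every MES sample scores far higher on the MES
signature than on the ADRN signature (0.97 vs 0.46), so the two states separate
with a wide margin. The other examples walk through SE calling and remodeling
(`02`), motif enrichment on induced regions (`03` — the planted RBPJ-style
motif is the only enriched one, Bonferroni p ≈ 8 × 10⁻⁵), and the feed-forward
time course (`04` — ADRN repression onset at day 1 precedes MES induction at
day 7; a 7-day transient induction stays transitioned after washout while a
3-day pulse reverts; the gamma-secretase inhibitor scenario is blocked).

A thin CLI mirrors the library:

```bash
adrnmes simulate --preset chip --seed 7 --out-dir out/
adrnmes call-se --track out/h3k27ac_mes.bedgraph --out out/se.bed
adrnmes run-all --seed 1 --out-dir out/run
```

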