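"""Motif enrichment on regions with induced H3K27ac signal.

Builds the default landscape, selects the regions whose H3K27ac increased
beyond Poisson noise after induction, scans the bundled synthetic motifs
(an RBPJ-style consensus that the generator plants at 5x background rate
inside MES super-enhancers, an unplanted HES-style motif and a
column-shuffled control) and prints the Fisher/Bonferroni table.
"""

import warnings

from adrnmes import SimulationConfig, simulate_chip_landscape
from adrnmes import enhancers as enh
from adrnmes.motifs import demo_motif_path, load_jaspar, motif_enrichment, scan_motif
from adrnmes.simulate import default_genome

genome = default_genome()
track_a, track_b, genome_seq, truth = simulate_chip_landscape(
    SimulationConfig(seed=7), genome
)

norm_a = enh.normalize_track(track_a)
norm_b = enh.normalize_track(track_b)
peaks = enh.call_peaks(norm_b, enh.auto_threshold(norm_b), min_width=200)
regions = enh.stitch_peaks(peaks)
diffs = enh.poisson_direction_filter(
    enh.differential_surface(norm_a, norm_b, regions), track_a, track_b
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    induced = enh.select_induced_regions(diffs, 500)
background = [
    r.interval
    for r in regions
    if not any(r.start < e and s < r.end for s, e in induced)
]
print(f"{len(induced)} induced regions vs {len(background)} background regions")

pwms = load_jaspar(demo_motif_path())
hitsets = [scan_motif(genome_seq.sequence, p, score_fraction=0.8) for p in pwms]
results = motif_enrichment(induced, background, hitsets)
print()
print(f"{'motif':<16}{'fg':>6}{'bg':>9}{'p_raw':>12}{'p_bonf':>12}  enriched")
for r in results:
    print(
        f"{r.motif_id:<16}{r.fg_hit:>3}/{r.fg_hit + r.fg_miss:<3}"
        f"{r.bg_hit:>4}/{r.bg_hit + r.bg_miss:<4}"
        f"{r.p_raw:>12.3g}{r.p_bonferroni:>12.3g}  {r.enriched}"
    )
print()
print(
    "Only the planted RBPJ-style motif is significantly enriched in the"
    " induced regions; the shuffled control has the same base composition"
    " but no planted sites, so its p-value stays at ~1."
)
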