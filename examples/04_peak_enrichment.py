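"""Hexamer enrichment inside TF-binding peaks.

Compares, for each hexamer, the proportion of 6-bp positions it occupies
inside (merged) peak intervals against the same proportion across all
promoter windows, with a one-tailed Fisher exact test Bonferroni-corrected
over the 2080 hexamers (FWER < 0.05).  Peaks here are simulated centred on
planted TGTCTC instances, mimicking ARF-binding regions.
"""

from cishex import peak_enrichment
from cishex.simulate import PeakConfig, PlantedMotif, SimConfig, simulate

data = simulate(SimConfig(
    n_genes=400, window_len=400, seed=11,
    planted_motifs=(PlantedMotif("TGTCTC", "up", p_fg=0.9, p_bg=0.1),),
    peak_cfg=PeakConfig(n_peaks=80, width=80, frac_centered=1.0),
))
results = peak_enrichment(data.peaks, data.genome, data.promoters)

significant = [r for r in results if r.significant]
print(f"{len(significant)} hexamers enriched in peaks at FWER < 0.05")
for r in sorted(significant, key=lambda r: r.fwer_p)[:5]:
    fg = r.occupied_fg / r.total_fg
    bg = r.occupied_bg / r.total_bg
    print(f"  {r.feature}: fg {fg:.4f} vs bg {bg:.4f}  fwer_p={r.fwer_p:.3g}")
# The planted hexamer's canonical form GAGACA tops the list: its positional
# density under the peaks is an order of magnitude above the promoter-wide
# background.
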