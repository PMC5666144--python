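"""Marker-trait association on a fertile/sterile progeny panel.

One extra cross of a fertile line to the recurrent parent yields progeny
segregating ~1:1 for fertility.  Fisher's exact test per genotyped
marker, Bonferroni-corrected, localizes the trait to the FS interval.
"""

import numpy as np

import tricross as tc
from tricross.inheritance_stats import (
    associate_markers,
    rank_candidate_locus,
    segregation_test,
)

cfg = tc.SimConfig(seed=4)
gmap = tc.make_genome_map(cfg)
rng = np.random.default_rng(cfg.seed)

panel = tc.simulate_association_panel(cfg, rng, gmap=gmap)
print(f"panel: {cfg.panel_fertile} fertile + {cfg.panel_sterile} sterile "
      f"progeny, {len(panel.genotypes.markers)} markers")
p_seg = segregation_test(panel.n_fertile_draws, panel.n_draws - panel.n_fertile_draws)
print(f"fertile:sterile among {panel.n_draws} draws -> exact binomial "
      f"p = {p_seg:.3f} vs 1:1\n")

results = associate_markers(panel.genotypes, panel.phenotypes, "bonferroni")
print("marker              p          adjusted_p  direction")
for r in sorted(results, key=lambda r: r.p_value)[:6]:
    print(f"{r.marker[0]}:{r.marker[1]:<12} {r.p_value:.3e}  "
          f"{r.adjusted_p:.3e}  {r.odds_direction}")

locus = rank_candidate_locus(results, truth_locus=gmap.selected_loci["FS"])
print(f"\ncandidate locus: {locus.group_id}:{locus.start:,}-{locus.end:,} "
      f"({len(locus.markers)} adjacent significant markers)")
print(f"true FS marker inside: {locus.contains_truth}")
# Markers inside the FS donor block co-segregate almost perfectly with
# fertility (p ~ 1e-11 before correction); markers on other linkage
# groups stay non-significant, mirroring single-locus inheritance.
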