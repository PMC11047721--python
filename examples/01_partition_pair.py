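"""Partition the dissimilarity of a single pair of transects.

Two stream transects share one species (a=1); each also holds species the
other lacks (b=2, c=1). The Sørensen dissimilarity splits exactly into a
turnover part (species replacement) and a nestedness part (richness
difference of otherwise-shared composition).
"""

import streambeta as sb

low = [1, 1, 1, 0]   # low-elevation transect: 3 species
high = [0, 0, 1, 1]  # high-elevation transect: 2 species

pc = sb.pair_counts(low, high)
bp = sb.beta_pair(pc)

print(f"shared a={pc.a}, unique b={pc.b}, c={pc.c}")
print(f"beta_sor = {bp.beta_sor:.3f}  (total dissimilarity)")
print(f"beta_sim = {bp.beta_sim:.3f}  (turnover: replacement between sites)")
print(f"beta_sne = {bp.beta_sne:.3f}  (nestedness: ordered richness loss)")
print(f"identity: beta_sim + beta_sne = {bp.beta_sim + bp.beta_sne:.3f}")
# beta_sne/beta_sor < 0.5 would mean replacement, not species loss,
# dominates this pair's dissimilarity
print(f"beta_ratio = {bp.beta_sne / bp.beta_sor:.3f}")
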