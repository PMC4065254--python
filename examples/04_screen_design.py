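"""Size a whole screen under the FDR-nonempty discovery criterion.

How many kindreds must be phenotyped (at 20 progeny each) so the
Benjamini-Hochberg list at q = 0.05 contains, with 95% probability, at
least one kindred truly carrying a >= 2-fold enhancer? And how much does
preselecting kindreds with multiple extreme animals help?
"""

import minmod as mm
from minmod.design import ScreenDesign, preselected_design, screen_size_for_discovery
from minmod.enrichment import SelectionRule, extreme_selection_enrichment

baseline = mm.NegativeBinomialPhenotype()
# modifier mixture with a broad effect spread so 2-fold enhancers exist
mixture = mm.MixtureParams(
    weights=(0.39, 0.41, 0.20),
    suppressor=mm.TruncatedLogNormalEffect.suppressor(0.6, 0.4),
    enhancer=mm.TruncatedLogNormalEffect.enhancer(1.8, 0.4),
)
design = ScreenDesign(mixture=mixture, baseline=baseline)

n_plain = screen_size_for_discovery(design, n_progeny=20, effect_threshold=2.0,
                                    mc_reps=4000, seed=2)
print(f"unselected screen: {n_plain} kindreds x 20 progeny")

# preselect kindreds with >= 2 of 8 animals in the top 5% of counts
rule = SelectionRule(min_extreme=2, cluster_size=8, extreme_quantile=0.05,
                     tail="upper")
enrich = extreme_selection_enrichment(design.mixture, baseline, rule, 2.0)
n_sel, n_prog = preselected_design(design, rule, 20, 2.0, mc_reps=4000, seed=2)
print(f"extreme-kindred enrichment for >=2-fold enhancers: {enrich:.1f}x")
print(f"preselected screen: {n_sel} kindreds x {n_prog} progeny")

# Selecting kindreds that already produced two short-lived animals
# enriches several-fold for large enhancers, shrinking the screen by
# roughly that factor.
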