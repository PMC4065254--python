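"""How many progeny does a kindred need to reveal its modifier?

Power of the kindred-mean test (null: NB(99.8, 9.8) counts, no
modifier) for a segregating modifier of a given fold effect, as a
function of cluster size, plus the smallest cluster reaching 90% power.
"""

from minmod.power import DesignQuery, kindred_power, progeny_for_power

print("fold   n=10   n=20   n=30   progeny for 90% power")
for fold in (0.25, 0.5, 2.0, 4.0):
    powers = [
        kindred_power(DesignQuery(fold_effect=fold, progeny=n))
        for n in (10, 20, 30)
    ]
    need = progeny_for_power(DesignQuery(fold_effect=fold, progeny=1),
                             power_target=0.9)
    print(f"{fold:4.2f}  " + "  ".join(f"{p:5.3f}" for p in powers)
          + f"   {need:3d}")

# Large effects (4-fold, or 4-fold reduction) are detectable with a
# handful of progeny; a 2-fold enhancer needs about 10; weaker effects
# need clusters far beyond a single litter, which is why kindred founders
# are cryopreserved for retesting.
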