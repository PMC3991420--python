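"""Fixed vs random mappings: is one mapping per instrument enough?

Fits both models and compares them on DIC. A large DIC gap in favour of
the random-mapping model says mapping ratios genuinely differ from trial
to trial.
"""

import synthmap as sm

table = sm.load_as_trials()
rho = sm.load_easiqol_correlations()
signs = sm.derive_signs(rho, "PAIN-VAS")
blocks = sm.assemble_blocks(table, rho)

rows = []
for name, fit in [("fixed", sm.fit_fixed_mapping), ("random", sm.fit_random_mapping)]:
    res = fit(blocks, signs, reference="PAIN-VAS", seed=2)
    rep = sm.deviance_report(blocks, res)
    rows.append((name, rep.dbar, rep.pD, rep.dic))
    print(f"{name:>6}: Dbar={rep.dbar:5.1f}  pD={rep.pD:4.1f}  DIC={rep.dic:5.1f}")

gap = rows[0][3] - rows[1][3]
print(f"\nDIC difference (fixed - random) = {gap:.1f}")
print("Positive gap: the data reject identical mappings across trials;")
print("the 32 data points sit closer to the number Dbar reaches only under"
      " trial-level mappings.")
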