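"""Fit ER and ARD Mk models and compare them by AIC.

A binary trait is simulated under equal rates (ER) on a 200-tip Yule tree;
refitting both models shows the AIC penalty correctly favouring the
1-parameter ER model over the 2-parameter ARD model.
"""

from tmetrace import RateMatrix2, compare_aic, fit, marginal_ancestral, RootPrior
from tmetrace.synthetic_data import simulate_mk, yule_tree

tree = yule_tree(200, seed=42)
h = tree.height()
q_true = 0.5 / h
rec = simulate_mk(tree, RateMatrix2(q_true, q_true), root_state=1, seed=43)

er = fit(tree, rec.tips, model="ER")
ard = fit(tree, rec.tips, model="ARD")
for row in compare_aic([er, ard]):
    print(
        f"{row['model']:3s}  logL={row['loglik']:8.3f}  AIC={row['aic']:8.3f}  "
        f"dAIC={row['delta_aic']:6.3f}  q01={row['rates']['q01']:.4f}  q10={row['rates']['q10']:.4f}"
    )
print(f"\ntrue rate: {q_true:.4f} (both directions)")

post = marginal_ancestral(tree, rec.tips, er.rates, RootPrior("flat"))
print(f"root P(present) under the ER fit: {post[tree.root]:.3f}")
print(
    "\nThe model with the lowest AIC wins; with truly equal rates the extra"
    "\nARD parameter buys little likelihood and is penalized."
)
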