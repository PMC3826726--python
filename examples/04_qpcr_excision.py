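"""qPCR quantification of element excision under DNA damage.

Simulates dilution series and Ct tables for the integrated (attR) and
excised (attB) junction amplicons, fits standard curves, derives the
reaction efficiency E = 10^(-1/slope) - 1 and reports fold induction of
each form under mitomycin C relative to untreated control.
"""

from mgescan import simulate_qpcr_table
from mgescan.qpcr import analyze_qpcr

dilutions, samples = simulate_qpcr_table(
    efficiencies={"attR": 0.95, "attB": 0.90},
    quantities={
        ("attR", "control"): 0.02, ("attR", "mitomycinC"): 0.016,
        ("attB", "control"): 0.005, ("attB", "mitomycinC"): 0.030,
    },
    noise_sd=0.1, seed=8)

curves, folds = analyze_qpcr(samples, dilutions)
for target, curve in curves.items():
    print(f"{target}: slope {curve.slope:.3f}, E = {curve.efficiency:.3f}, "
          f"r^2 = {curve.r_squared:.4f}")
for f in folds:
    print(f"{f.target} under {f.condition}: fold {f.fold:.2f} "
          f"(replicate spread {f.spread[0]:.2f}-{f.spread[1]:.2f})")
print("The excised form (attB) is induced ~6-fold by DNA damage while the "
      "integrated form (attR) stays near 1 — the signature of damage-"
      "triggered excision.")
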