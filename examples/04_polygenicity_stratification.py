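"""Stratify traits by polygenicity and watch score inflation grow.

Builds five groups of traits with rising numbers of causal variants at
fixed total signal, estimates each trait's corrected genomic inflation
factor lambda_GC^c = lambda_GC - (LDSC intercept - 1), bins traits by it,
and re-runs the scoring pipeline per bin. More polygenic bins show more
median inflation of the LD-corrected magnitude score: polygenicity alone
produces horizontal pleiotropy.
"""

import numpy as np

import pleioscore as ps
from pleioscore.io import SummaryMatrix, _empty_trait_meta

n, n_per = 60_000, 12
pattern = [1, 2, 5, 10, 20]
ld = ps.make_ld_structure(n, block_size=pattern, rho=0.8)
total_signal = 18_000.0  # sum of effective_n * h2 over causal variants
cols = []
for r, n_causal in enumerate([150, 600, 2400, 9600, 38400]):
    cfg = ps.SimulationConfig(
        n_variants=n, n_traits=n_per, h2=total_signal / n_causal / 1e4,
        prop_pleio=0.0, prop_nonpleio=n_causal / n, nu=1,
        ld_block_size=pattern, ld_rho=0.8, seed=123 + r,
    )
    m, _, _ = ps.simulate_dataset(cfg)
    cols.append(m.z)
traits = _empty_trait_meta([f"r{r}_t{j}" for r in range(5) for j in range(n_per)])
matrix = SummaryMatrix(np.concatenate(cols, axis=1), m.variants, traits)

estimates = ps.estimate_polygenicity(matrix, ld)
bins = ps.stratify_and_rescore(matrix, estimates, n_h2_classes=1,
                               n_poly_bins=5, ld=ld)
print("bin  mean lambda_GC^c  median -log10 P(Pm_LD)")
for b in range(5):
    ids = bins[(0, b)]["traits"]
    lam = np.mean([e.lambda_gc_corrected for e in estimates
                   if e.trait_id in ids])
    p = np.maximum(bins[(0, b)]["result"].table["p_m"], 1e-300)
    med = np.median(-np.log10(p))
    print(f"{b}    {lam:15.3f}  {med:21.3f}")
# Both columns rise together across bins: the corrected inflation factor
# ranks traits by polygenicity, and pleiotropy-score inflation follows it.
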