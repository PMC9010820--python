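"""Recover immune-cell fractions from noisy mixtures by constrained fitting.

Simulates a nine-cell-type reference signature, mixes it with known
Dirichlet fractions under 10% multiplicative noise, and re-estimates the
fractions by row-scaled non-negative least squares with sum-to-one
renormalization.  The mean absolute error per fraction summarizes
recovery quality.
"""

import numpy as np
import pandas as pd

import stromacomp as sc

signature = sc.simulate_signature_matrix(seed=7)
rng = np.random.default_rng(8)
true_fractions = pd.DataFrame(
    rng.dirichlet(np.ones(signature.n_cell_types), size=50),
    index=[f"MIX{i:02d}" for i in range(50)],
    columns=signature.cell_types,
)

mixtures, truth = sc.generate_mixtures(signature, true_fractions, noise_cv=0.1, seed=9)
result = sc.deconvolve(mixtures, signature)

err = np.abs(result.fractions - true_fractions)
print(f"samples: {len(true_fractions)}, cell types: {signature.n_cell_types}")
print(f"mean absolute fraction error: {err.to_numpy().mean():.4f}")
print(f"worst single fraction error:  {err.to_numpy().max():.4f}")
print("\nfirst mixture, true vs estimated:")
print(
    pd.DataFrame(
        {"true": true_fractions.iloc[0], "estimated": result.fractions.iloc[0]}
    ).round(3)
)
# Errors well below 0.05 per fraction mean the mixing proportions are
# identifiable from the signature despite the measurement noise.
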