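"""Sample and calibrate a dominant trait architecture.

QTL additive effects have gamma(0.4, 1.66) magnitudes with random sign,
degrees of dominance are N(0.5, 1), and effects are rescaled so the
additive (breeding-value) variance is 0.3 and the dominance-component
variance hits the model's target (0.1 for Models 1/3, 0.05 for Model 2).
The share of QTL left over-dominant (|d| > |a|) is an emergent property
of that calibration.

Run:  python examples/02_trait_architecture.py
"""
import numpy as np

from heterosim import compute_variances, sample_effects, scale_effects
from heterosim.config import trait_config_for_model

rng = np.random.default_rng(2)
# stand-in for base-population QTL frequencies (drifted, MAF > 0.05)
base_freqs = rng.beta(0.6, 0.6, 400)
base_freqs = 0.05 + 0.9 * base_freqs

for model_id in (1, 2, 3):
    trait = trait_config_for_model(model_id)
    od = []
    for _ in range(10):
        eff = scale_effects(sample_effects(400, model_id, rng),
                            base_freqs, trait)
        od.append(100 * eff.overdominant.mean())
    va, vd = compute_variances(eff, base_freqs)
    print(f"Model {model_id}: sigma2_a={va:.4f} (target "
          f"{trait.sigma2_a_target}), sigma2_d={vd:.4f} (target "
          f"{trait.sigma2_d_target}), over-dominant QTL "
          f"{np.mean(od):.1f}% over 10 draws")
print("Model 1 keeps substantial over-dominance, Model 2 about half as "
      "much, Model 3 none by construction.")
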