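"""Small end-to-end SOM mapping experiment on a synthetic scene.

Generates a 64x64 scene with known ground truth, assembles the
environmental (Ev) and composite (Ev-Tn-Mm) feature sets, cross-validates
a random forest on both, and prints the accuracy plus the top variable
importances. (The full 200x200 / n=500 benchmark with the CNN is what
scripts/acceptance.py runs; this keeps the example under ~30 s.)
"""

from somfuse import RfSpec, RunConfig, run
from somfuse.synthetic import SceneRecipe

recipe = SceneRecipe(rows=64, cols=64, n_years=2, n_samples=150,
                     measurement_noise_sd=0.25 * 2.42, seed=11)
config = RunConfig(recipe=recipe, seed=11, folds=5, models=("rf",),
                   rf=RfSpec(n_estimators=100, max_depth=6))
report = run(config)

print("out-of-fold accuracy (5-fold CV pooled, g/kg):")
for key, rep in report["evaluations"].items():
    print(f"  {key:14s} MAE {rep['mae']:.3f}  RMSE {rep['rmse']:.3f}  "
          f"R2 {rep['r2']:.3f}")

print("\nEv -> Ev-Tn-Mm derived statistics (%):")
for k, v in report["derived"]["rf"].items():
    print(f"  {k:28s} {v}")

imp = sorted(report["importance"]["per_feature"].items(),
             key=lambda kv: -kv[1])[:5]
print("\ntop-5 variable importances (% of total):")
for name, pct in imp:
    print(f"  {name:16s} {pct:5.1f}")

print("\nThe composite feature set should match or beat Ev alone. In this")
print("recipe the long-term NDVI statistics carry a strong SOM-linked")
print("productivity signal, so they lead the importance ranking, followed")
print("by the soil-moisture covariates.")
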