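"""Paired comparison of two model variants with McNemar's test.

Trains the full two-pass-attention hybrid and the plain-concatenation
ablation on the same split, then compares their test predictions through
the discordant counts (exact binomial p-value for small counts).
"""

from cramnet import metrics, pipeline, synth
from cramnet import model as M

split = synth.generate_dataset(60, (0.667, 0.167, 0.166), 1, seed=11)

models = {}
for mode in ("cram", "none"):
    m = M.build_model(attention_mode=mode, seed=0)
    m, _ = M.train(m, split, M.desk_scale_config(seed=0, max_epochs=6))
    models[mode] = pipeline.evaluate_split(m, split.test)

for mode, ev in models.items():
    print(f"attention={mode:5s}: test accuracy {ev['summary']['accuracy']:.2f}%")

b, c = metrics.discordant_counts(models["cram"]["pred"], models["none"]["pred"],
                                 models["cram"]["true"])
print(f"\ndiscordant counts: attention-only correct b={b}, ablation-only correct c={c}")
if b + c == 0:
    print("-> the two variants agree on every test image; McNemar's test is")
    print("   undefined (no discordant pairs), i.e. no evidence of a difference.")
else:
    res = metrics.mcnemar(b, c)
    print(f"McNemar chi2 = {res.chi2:.3f}, p = {res.p:.3f} ({res.method})")
    print("-> the test uses only the images the two classifiers disagree on;")
    print("   a large p means the symmetric-disagreement null cannot be rejected.")
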