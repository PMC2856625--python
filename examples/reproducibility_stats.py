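"""Reproducibility of the assay: CV levels, ANOVA shares, replicate pairs.

Runs the full replication design (6 sera, each on 6 arrays per slide, one
slide per day over 3 days = 18 replicate arrays, plus 36 mocks), then asks:
how much do replicate measurements of the same serum vary (CV at three
replication levels), which design factors drive the total variance (ANOVA),
and how well do replicate arrays agree pairwise (regression slope / R^2)?
"""

import pandas as pd

import serochip as sc
from serochip import experiments
from serochip.pipeline import _long_table

config = sc.SimulationConfig(seed=0)
scans, truth = sc.simulate_study(config)
mocks = [s for s in scans if s.meta.is_mock]
samples = [s for s in scans if not s.meta.is_mock]
model = sc.calibrate([sc.preprocess(s) for s in mocks], config.layout)
processed = [sc.apply_thresholds(sc.correct(sc.preprocess(s), model), model)
             for s in samples]
per_array = sc.build_ige_matrix(processed, config.layout, model,
                                collapse_replicate_arrays=False)
long = _long_table(per_array, truth.manifest)

print("Median CV (sd/mean of replicates, cells with mean > 0.5):")
for level in ("intra-slide", "inter-slide", "inter-assay"):
    rep = sc.cv_report(long, level, classes=config.layout.allergen_classes)
    med = rep.per_cell["cv"].median()
    print(f"  {level:12s} {med:.3f}  ({len(rep.per_cell)} cells)")

print("\nANOVA variance shares (sequential SS):")
aov = sc.anova_components(long)
print(aov.table.round(2))

res = experiments.replicate_concordance(seed=0)
print(f"\nReplicate-array concordance over {res.n_pairs} pairs:")
print(f"  median R^2   = {res.median_r_squared:.3f}")
print(f"  median slope = {res.median_slope:.3f}")
print("\nBiological factors (which allergen, which serum) carry the")
print("systematic variance while array- and slide-level shares stay near")
print("zero — the signature of a reproducible assay.  High median R^2 and")
print("a slope near 1 say the same thing at the level of replicate pairs.")
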