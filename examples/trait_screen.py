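"""Screen pollen traits for within-taxon stability and between-taxon
discrimination.

Generates a synthetic germplasm panel (23 species + 84 cultivars, 30
replicate measurements per trait) and runs the two coefficient-of-
variation statistics: cvbar (mean within-taxon CV; <= 15% means the
trait replicates stably inside a taxon) and cv (CV of the per-taxon
means; >= 15% means the trait spreads taxa apart). A good
identification index is uniform AND distinct.
"""

from pollenstats import SimConfig, generate_study, uniformity_distinctness_report

study = generate_study(SimConfig(seed=42))
report = uniformity_distinctness_report(study.table)

print(report[["trait", "cvbar", "uniform", "cv", "distinct"]]
      .round(3).to_string(index=False))
print()
good = report[report["uniform"] & report["distinct"]]["trait"].tolist()
print(f"uniform AND distinct -> usable identification indices: {good}")
print("(furrow width and perforation density replicate too noisily "
      "within a taxon to be reliable, despite discriminating strongly)")
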