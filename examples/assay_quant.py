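"""Quantify qPCR and ELISA plates against their standard curves.

Fits the per-plate log-linear qPCR curve (gated at R^2 > 0.9), quantifies
samples with housekeeping normalization, then fits a 4PL ELISA curve and
reports pg analyte per mg tissue.
"""

import numpy as np

from ablaquant import assays, synth

qpcr, elisa, truth = synth.gen_assay_fixtures(
    synth.AssaySpec(seed=9, cq_noise_sd=0.2, elisa_noise_sd=0.01))

std = qpcr[qpcr.role == "standard"]
fit = assays.fit_standard_curve(assays.DilutionSeries(
    tuple(std.concentration), tuple(std.cq)))
print(f"qPCR curve: slope {fit.slope:.4f} (efficiency "
      f"{100 * fit.efficiency:.1f}%), R^2 = {fit.r_squared:.4f}, "
      f"usable: {fit.usable}")

samples = qpcr[qpcr.role == "sample"]
r18s_abundance = 500.0  # housekeeping abundance of the same sample
for _, row in samples.iterrows():
    q = assays.quantify_qpcr(row.cq, fit, reference_quantity=r18s_abundance)
    print(f"  {row['sample']}: Cq {row.cq:.2f} -> {q.raw:.1f} "
          f"(normalized to R18S: {q.normalized:.3f})")

estd = elisa[elisa.role == "standard"]
f4 = assays.fit_4pl(assays.DilutionSeries(tuple(estd.concentration),
                                          tuple(estd.absorbance)))
print(f"\nELISA 4PL: a={f4.a:.3f} b={f4.b:.3f} c={f4.c:.1f} d={f4.d:.3f}")
for _, row in elisa[elisa.role == "sample"].iterrows():
    conc = assays.invert_4pl(row.absorbance, f4)
    per_mg = assays.normalize_per_mg(conc.raw, row.eluate_volume_ml,
                                     row.tissue_mass_mg)
    print(f"  {row['sample']}: A={row.absorbance:.3f} -> "
          f"{conc.raw:.1f} pg/ml -> {per_mg:.2f} pg/mg tissue")
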