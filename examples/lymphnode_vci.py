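"""Classify lymph-node vasculature and compute the Vascular Complexity Index.

Generates a CD31/LYVE-1/DAPI field with known vessel classes, segments
CD31+ objects as sub-pixel contours, splits them into lymphatic
(LYVE-1+) versus blood (LYVE-1-) vessels, filters sub-15 um^2 specks, and
summarizes each class per node: count, area percent, and VCI.
"""

import numpy as np

from ablaquant import lymphnode as ln, synth

spec = synth.LymphNodeSpec(seed=5, shape=(512, 512))
scene = synth.gen_if_lymphnode(spec)
truth_counts = scene.truth["class"].value_counts().to_dict()
print("ground truth:", truth_counts)

# a normalized CD31 channel stands in for the pixel-classifier output here;
# see train_pixel_classifier for the learned version
prob = np.clip((scene.channels["cd31"] - 60.0) / 80.0, 0.0, 1.0)
objects = ln.segment_vessels(prob, threshold=0.5,
                             pixel_size_um=spec.pixel_size_um,
                             cd31=scene.channels["cd31"],
                             lyve1=scene.channels["lyve1"])
objects = ln.filter_by_area(objects, min_area_um2=15.0)
objects = ln.classify_objects(objects, lyve1_background=(spec.background,
                                                         spec.noise_sd))
record = ln.summarize_node(scene.node_polygon_um,
                           scene.artifact_polygons_um, objects)
print(f"net node area: {record.net_area_mm2:.3f} mm^2")
for cls, s in record.summaries.items():
    print(f"{cls:>10}: n={s.count}  area={s.area_percent:.3f}% of node  "
          f"VCI={s.vci:.2f}")
print("a single perfect circle would give VCI = 1; n identical circles n")
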