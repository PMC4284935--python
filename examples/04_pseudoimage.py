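"""Render the false-color Hb pseudoimage for one disc.

Writes pseudoimage.png: the per-pixel Hb map on a perceptually ordered
palette with a 0-120% colorbar; pixels outside the disc render neutral.
"""

from onhcolor.hb import save_pseudoimage
from onhcolor.pipeline import analyze_fundus
from onhcolor.synth import SubjectSpec, render_fundus

rendered = render_fundus(SubjectSpec(subject_id="demo", seed=11))
result = analyze_fundus(rendered.image)
save_pseudoimage(result.hb_map, "pseudoimage.png")
print(f"mean Hb {result.profile.mean_hb:.2f}% -> pseudoimage.png")
print("Warm (bright) colors mark well-perfused tissue near the vessel")
print("reference; dark colors mark pale, Hb-poor areas such as the cup.")
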