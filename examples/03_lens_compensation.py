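"""Effect of lens (cataract) yellowing and its compensation.

A yellowed lens attenuates blue (factor kappa) and green (about half as
much), which inflates the red-green Hb index.  The compensation estimates
kappa from the vessels' blue/green ratio and rescales green before the
index is formed.
"""

from dataclasses import replace

from onhcolor.pipeline import analyze_fundus
from onhcolor.synth import SubjectSpec, render_fundus

base_spec = SubjectSpec(seed=42)
clear = analyze_fundus(render_fundus(base_spec).image).profile.mean_hb
print(f"clear lens (kappa=1.0): mean Hb {clear:.2f}%")

for kappa in (0.9, 0.8, 0.7, 0.6):
    img = render_fundus(replace(base_spec, kappa=kappa)).image
    with_comp = analyze_fundus(img)
    without = analyze_fundus(img, lens_compensation=False).profile.mean_hb
    print(f"kappa={kappa:.1f}: compensated {with_comp.profile.mean_hb:6.2f}% "
          f"(kappa_hat {with_comp.compensation.kappa_hat:.3f})   "
          f"uncompensated {without:6.2f}%")

print("\nCompensated estimates stay within ~2 points of the clear-lens value;")
print("uncompensated ones drift upward as the lens yellows, because green is")
print("attenuated and the red-green contrast grows spuriously.")
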