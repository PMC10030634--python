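"""Body-part surface areas from morphometric dimensions.

Computes the sphere/ellipsoid approximations of the forager body and
compares them with the published part areas that ship as the default
preset.
"""
from beeheat import REFERENCE_DIMENSIONS, body_surface

published = body_surface()  # published areas, published total
computed = body_surface(REFERENCE_DIMENSIONS)  # from (reconstructed) dimensions

print("part       published mm^2   computed mm^2")
for key, label in (("A_hd", "head"), ("A_th", "thorax"), ("A_ab", "abdomen"), ("A_b", "body")):
    print(f"{label:<10}{published.as_mm2()[key]:>13.2f}{computed.as_mm2()[key]:>16.2f}")

# The published total (163.7 mm^2) is smaller than the sum of the
# published parts (164.49 mm^2); both are carried, nothing is corrected.
print(f"\nsum of published parts: {body_surface(total='sum').as_mm2()['A_b']:.2f} mm^2")
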