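"""Extract the 17-feature radiomic panel from one synthetic tumour phantom.

Builds a CT-like textured ellipsoid, then extracts shape, first-order, GLCM
and NGTDM features under the harmonised calculation settings (64 grey levels
over the ROI range, 13 co-occurrence directions at offset 1, NGTDM distance 1).
"""

from radharm import PhantomSpec, builtin_profile, extract_single, generate_phantom

phantom = generate_phantom(PhantomSpec(seed=42))
profile = builtin_profile("harmonised")
features = extract_single(phantom, profile)

print(f"phantom: {phantom.n_voxels} ROI voxels at {phantom.spacing} mm spacing")
for name, value in features.items():
    print(f"  {name:28s} {value:12.4f}")

# volume/area are in mm^3/mm^2, intensities in HU; sphericity is 1 for a
# perfect sphere; the texture values depend on the profile's discretisation
# settings and would differ under another platform's defaults.
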