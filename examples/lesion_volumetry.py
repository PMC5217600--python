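"""Threshold-planimetry volumetry of T2-like and TTC-like slice stacks.

Plants ellipsoidal lesions of known volume (the two published group means),
then recovers them with the analysis pipeline: 3 × 3 Gaussian smoothing,
per-slice threshold at 75% of the maximum, area × slice-thickness summation.
"""

from speckleflow import infarct_volume, lesion_volume, make_lesion_volume

print("T2-like MRI stack: 20 slices x 1 mm, 0.1 mm pitch")
mri = make_lesion_volume(63.7, n_slices=20, thickness_mm=1.0, in_plane_pitch_mm=0.1, seed=9)
res = lesion_volume(mri)
print(f"  planted lesion volume  : 63.70 mm^3")
print(f"  recovered lesion volume: {res.total_volume_mm3:.2f} mm^3")
print(f"  lesion-bearing slices  : {sum(a > 0 for a in res.per_slice_area_mm2)}")

print("\nTTC-like stack: 6 slices x 3 mm (pale infarct bright)")
ttc = make_lesion_volume(
    32.0, n_slices=6, thickness_mm=3.0, in_plane_pitch_mm=0.1, seed=9, modality="TTC-like"
)
res = infarct_volume(ttc)
print(f"  planted infarct volume  : 32.00 mm^3")
print(f"  recovered infarct volume: {res.total_volume_mm3:.2f} mm^3")
print("\nrecovery error stays within the one-voxel rasterization shell plus the")
print("~1-px boundary blur of the smoothing kernel.")
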