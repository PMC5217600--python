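"""Raw speckle → hypoperfused-area pipeline on a synthetic occlusion.

Plants a focal occlusion whose >50%-flow-reduction territory reaches
12.4 mm² after 15 min, renders time-integrated dynamic speckle before and
after, and recovers the territory area from the raw frames alone.
"""

import speckleflow as sf

cfg = sf.ScenarioConfig(
    image_shape=(128, 128),
    pixel_pitch_mm=0.08,
    target_area_15min_mm2=12.4,
    seed=7,
)
n_frames = 12
dur = n_frames / cfg.frame_rate_hz / 60.0

print("rendering baseline and 15-min bins ...")
baseline = sf.render_sequence(cfg, -dur, 0.0)
post = sf.render_sequence(cfg, 15.0, 15.0 + dur)

flow_base = sf.contrast_to_flow(sf.spatial_contrast(baseline), T=cfg.exposure_s)
flow_post = sf.contrast_to_flow(sf.spatial_contrast(post), T=cfg.exposure_s)
nmap = sf.normalize_to_baseline(flow_post, flow_base)

hemi = cfg.hemisphere_mask()
area = sf.mask_area(sf.reduction_mask(nmap, hemi), cfg.pixel_pitch_mm)
truth = sf.make_flow_phantom(cfg, 15.0).true_reduction_area_mm2
occluded = sf.occlusion_success(nmap, sf.make_flow_phantom(cfg, 15.0).mca_core_mask)

print(f"planted >50%-reduction area : {truth:6.2f} mm^2")
print(f"recovered CBF_50 at 15 min  : {area:6.2f} mm^2 ({100 * (area / truth - 1):+.1f}%)")
print(f"occlusion success (>85% regional decrease at the focus): {occluded}")
print("CBF_50 is the pixel count with normalized flow N < 0.5 times pitch^2;")
print("small residual error comes from estimator noise at the territory edge.")
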