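"""Calibrate one synthetic fish photograph and measure its stripe metrics.

A synthetic lateral photograph carries an 18%-reflectance grey standard;
anchoring to it maps the sensor's linear response onto a 0-100 luminance
scale on which the standard reads 18.  The striped trunk then yields a
bimodal histogram whose two peaks are the dark- and light-stripe luminances.
"""

from stripelum import (
    apply_roi,
    calibrate,
    mean_luminance,
    measure_standard,
    stripe_peaks,
    weber_contrast,
)
from stripelum.synthetic import SyntheticImageSpec, generate_fish_image

spec = SyntheticImageSpec(seed=1)  # stripes at reflectance 0.09 / 0.27
image, truth = generate_fish_image(spec)

std = measure_standard(image, spec.standard_rect,
                       reflectance=spec.standard_reflectance)
cal = calibrate(image, std, px_per_mm=spec.px_per_mm)

sample = apply_roi(cal, truth.roi_mask)
l_min, l_max = stripe_peaks(sample)
cw = weber_contrast(l_max, l_min)

print(f"standard mean pixel value : {std.mean[0]:.1f}")
print(f"ROI mean luminance        : {mean_luminance(sample):.2f}  "
      f"(truth {truth.mean_luminance:.2f})")
print(f"dark stripe peak  L_min   : {l_min:.2f}  (truth {truth.l_dark:.1f})")
print(f"light stripe peak L_max   : {l_max:.2f}  (truth {truth.l_light:.1f})")
print(f"Weber contrast    C_W     : {cw:.3f}  (truth {truth.weber_contrast:.1f})")
# L_min/L_max are histogram-peak luminances of the two stripe classes;
# C_W = (L_max - L_min)/L_min is their relative contrast, ~2.0 here.
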