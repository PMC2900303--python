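"""Render a ratio frame in the standard pseudocolor convention.

Computes the 340/380 ratio stack of a short simulated session, scales
one frame to its session display range, and writes an 8-bit PNG where
low ratio (low Ca2+) is blue and high ratio (high Ca2+) is yellow/red.
"""
import furatrack as ft

scene = ft.preset("wildtype", seed=4, frames=120)
stack, _ = ft.simulate_scene(scene)
mask = ft.compute_embryo_mask(stack)
ratios = ft.compute_ratio(stack, mask)

lo, hi = ft.display_range(ratios)  # 1st/99th percentile of valid ratios
frame = 60
rgb = ft.encode_pseudocolor(ratios.ratio[frame], ratios.valid[frame], lo, hi)
path = ft.render_frame_png(rgb, "ratio_frame.png")
print(f"display range [{lo:.3f}, {hi:.3f}] mapped to 8-bit levels 0..255")
print(f"wrote {path}: frame {frame} with sustained stripes in warm colors, "
      "baseline tissue in blue/green, background black")
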