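"""The sanctioned preprocessing chain and what each stage contributes.

A scene is analysed as: green channel (for RGB input) -> small Gaussian
(kernel size 2 px, sigma 0.5) -> white top-hat (disk SE, radius 25 px).
The top-hat removes smooth illumination structure larger than the SE; the
demonstration below renders a scene with a strong multiplicative
illumination ramp and shows the left/right brightness imbalance shrinking
after correction.
"""

from backmatch import SceneSpec, preprocess_gray, render_scene

spec = SceneSpec(
    width=512, height=512, background_beta=2.0,
    illumination=(0.5, 512),  # 50% brightness ramp across the full width
    seed=3,
)
scene, truth = render_scene(spec)

left, right = scene[:, :256].mean(), scene[:, 256:].mean()
print(f"before correction: left half mean {left:.3f}, right half mean {right:.3f}")

gray = preprocess_gray(scene)
left2, right2 = gray.pixels[:, :256].mean(), gray.pixels[:, 256:].mean()
print(f"after  correction: left half mean {left2:.3f}, right half mean {right2:.3f}")
print(f"provenance: {[step for step, _ in gray.provenance]}")

print(
    "\nThe top-hat removes the smooth brightness offset (the absolute "
    "left/right difference drops severalfold); the residual reflects the "
    "multiplicative gain on texture contrast, which no subtractive "
    "correction can undo."
)
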