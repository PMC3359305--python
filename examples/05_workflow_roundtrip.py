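"""File-based round trip: generate a scene, map it, run the group stats.

The workflow functions mirror a config-first command-line habit: each takes
a plain dict (loadable from YAML/JSON), validates it, writes its outputs
plus a JSON RunReport holding every parameter and input hash, so any run
can be reproduced bit-identically from the report alone.
"""

import json
from pathlib import Path

from backmatch import run_generate, run_map, run_multipoint
from backmatch.regions import Region, RegionSet

root = Path("backmatch_example_output")
spec_path = Path(__file__).parent / "reference_scene.yaml"

gen = run_generate({"scene_spec": str(spec_path), "out": str(root / "scene")})
print("generated:", sorted(gen.outputs))

# annotate the regions (in a field study these come from a human annotator;
# here we know the layout from the scene spec)
rois = RegionSet(
    [
        Region("octopus_mantle", rect=(30, 30, 150, 150)),
        Region("distinct_object", rect=(255, 85, 150, 150)),
        Region("general_substrate", rect=(320, 320, 180, 180)),
    ],
    image_ref=gen.outputs["scene"],
)
roi_path = root / "roi.json"
rois.to_json(roi_path)

mapped = run_map({
    "image": gen.outputs["scene"], "roi": str(roi_path),
    "stride": 8, "out": str(root / "map"),
})
print("map:", *mapped.conclusions, sep="\n  ")

mp = run_multipoint({
    "image": gen.outputs["scene"], "roi": str(roi_path),
    "seed": 0, "out": str(root / "multipoint"),
})
print("multipoint:", *mp.conclusions, sep="\n  ")

report = json.loads(open(mp.outputs["report"]).read())
print("\nreport parameters:", report["parameters"])
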