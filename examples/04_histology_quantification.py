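"""Quantify fluorescent contrast-agent aggregates in synthetic sections.

One two-channel fixture per kinetic phase is segmented with the Fiji-style
pipeline (entropy thresholds, watershed nuclei splitting, 5-um^2 filter)
and summarised as placenta-normalised statistics.
"""

from placentadce import (
    generate_fluorescence_fixture,
    quantify,
    segment_aggregates,
    segment_nuclei,
    segment_placenta,
)

print("phase       true n  found n  relative area  small/medium/large")
for phase in ("elevation", "reduction", "recovery"):
    img, truth = generate_fluorescence_fixture(phase, seed=3)
    nuclei = segment_nuclei(img.blue)
    _, table = segment_aggregates(img.green, nuclei, img.pixel_size)
    placenta = segment_placenta(img.green, img.blue)
    stats = quantify(table, placenta, img.pixel_size)
    c = stats.count_by_class
    print(
        f"{phase:10s}  {len(truth):6d}  {stats.total_count:7d}  "
        f"{stats.relative_area:13.4f}  {c['small']}/{c['medium']}/{c['large']}"
    )
print(
    "-> aggregate coverage peaks during the signal-reduction phase and is\n"
    "   lowest during elevation, mirroring the in-vivo aggregation kinetics"
)
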