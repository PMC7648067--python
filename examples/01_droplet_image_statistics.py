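"""Segment condensate puncta in a synthetic two-channel frame and report the
condensate-formation ratio, partition coefficient and probe/scaffold ratio.

The frame emulates a cell expressing an mCherry-tagged scaffold (channel 0)
and a green interaction probe (channel 1): two droplets on a uniform
background, scaffold enriched 3.1-fold and probe 2.1-fold inside.
"""

from condensate_proximity import (
    DropletSpec,
    ImageSpec,
    condensate_fraction,
    generate_droplet_image,
    partition_coefficient,
    segment_puncta,
    signal_ratio,
)

spec = ImageSpec(height_px=192, width_px=192, pixel_size_um=0.1,
                 background_level=100.0, noise_sd=4.0, seed=42)
droplets = [
    DropletSpec((60.0, 60.0), radius_um=1.5, inside_over_outside=(3.1, 2.1)),
    DropletSpec((130.0, 120.0), radius_um=1.0, inside_over_outside=(3.1, 2.1)),
]
(scaffold, probe), truth_mask = generate_droplet_image(spec, droplets, n_channels=2)

puncta = segment_puncta(scaffold, min_area_um2=0.01)  # Otsu threshold
print(f"puncta detected: {puncta.n_puncta} (threshold {puncta.threshold:.1f} a.u.)")
print(puncta.regions.to_string(index=False))

frac = condensate_fraction(scaffold, puncta)
pc = partition_coefficient(scaffold, puncta)
ratio_cell = signal_ratio(probe, scaffold, truth_mask >= 0)
ratio_droplet = signal_ratio(probe, scaffold, puncta.mask)

print(f"condensate-formation ratio: {frac:.3f}")
print(f"partition coefficient:      {pc.pc:.2f} "
      f"(inside {pc.mean_inside:.1f} / outside {pc.mean_outside:.1f} a.u.)")
print(f"probe/scaffold ratio, whole cell: {ratio_cell:.3f}; in droplets: {ratio_droplet:.3f}")
# The PC near 3.1 recovers the simulated scaffold enrichment; the formation
# ratio is the fraction of total scaffold signal captured by the droplets.
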