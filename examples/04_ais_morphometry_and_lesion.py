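"""AIS length / soma distance from a fluorescence profile; lesion volume.

Builds a noisy trapezoidal Ankyrin-G profile with known 0.33-of-max
crossings, detects the AIS boundaries, measures the soma distance, and
computes a serial-section lesion volume.
"""

from strokephys import (
    detect_ais_bounds,
    distance_from_soma,
    lesion_volume,
    simulate_ais_profile,
    simulate_lesion_sections,
)

profile, truth = simulate_ais_profile(
    start_um=5.0, plateau_um=20.0, edge_um=1.0, f_max=1000.0, noise_sd=100.0, seed=7
)
bounds = detect_ais_bounds(profile, threshold_fraction=0.33, smooth_window_um=1.0)
soma = distance_from_soma(soma_end_um=2.0, ais_start_um=bounds.start_um)

print(f"AIS start  = {bounds.start_um:6.2f} um  (truth {truth.start_um:.2f})")
print(f"AIS end    = {bounds.end_um:6.2f} um  (truth {truth.end_um:.2f})")
print(f"AIS length = {bounds.length_um:6.2f} um  (truth {truth.length_um:.2f}; trapezoid closed form)")
print(f"distance from soma = {soma.distance_um:.2f} um (overlap flag: {soma.overlaps_soma})")

series = simulate_lesion_sections(true_volume_mm3=0.75, n_sections=12, seed=3)
print(f"lesion volume = {lesion_volume(series):.4f} mm^3 from {len(series.section_areas_um2)} "
      "sections (areas x 30 um thickness x series factor 3)")
print("At signal-to-noise 10 with 1-um smoothing the 0.33-of-max boundaries")
print("come back within ~0.1 um of the analytic crossings.")
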