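"""Cell tracking and directionality on a directed-motion movie.

Simulates dermomyotome-like cells drifting toward the rostro-medial
quadrant (+x medial, +y rostral; sink bearing 45°), runs the full
pipeline — invert / band-pass / rolling-ball preprocessing, LoG spot
detection, simple-LAP linking — and prints per-population statistics.
A mean resultant length R near 1 means concerted movement; near 0,
random movement.
"""

import numpy as np

from somitekit.io import VoxelGeometry
from somitekit.synth import TissueModel, simulate_movie, stage_preset
from somitekit.tracking import track_movie

geometry = VoxelGeometry()
domain = (110.0, 110.0, 4.0)
tissue = TissueModel(domain_um=domain, n_cells=40, radius_mean_um=3.0)
preset = stage_preset("mid", domain)  # directed, 0.21 µm/min

seq, truth = simulate_movie(
    tissue, preset["motion"], 8, geometry, seed=0, noise={"snr": 10}
)
tracks, stats = track_movie(
    seq, expected_diameter_um=5.0, quality_threshold=0.01, max_link_distance_um=12.0
)

print(f"tracks kept (≥3 frames): {stats['n_tracks']}")
print(f"mean speed             : {np.mean(stats['speeds_um_per_min']):.3f} µm/min "
      f"(generator mean 0.21)")
print(f"directionality R       : {stats['resultant_length']:.2f}")
print(f"mean track angle       : {stats['mean_angle_deg']:.0f}° "
      f"(sink bearing 45° = rostro-medial)")
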