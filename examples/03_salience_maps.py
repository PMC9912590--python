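"""Compute physical salience, motion salience, and luminance for one scene.

The static high-contrast patch should dominate the spectral-residual map,
the moving patch the Gaussian-mixture foreground map, and the per-frame
summaries express each map's mean as percent of its maximum.
"""

import numpy as np

from gazesal import ScreenGeometry, compute_scene_features, scene_salience_summary
from gazesal.synth import SceneSpec, generate_video

geometry = ScreenGeometry(width_px=128, height_px=96)
video = generate_video(
    SceneSpec("demo", "non-human", 2000.0, moving_speed_px=3.0), geometry, seed=2
)
maps = compute_scene_features(video.frames)

frame = 30
phys = maps[frame].physical_salience
motion = maps[frame].motion_salience
x0, y0, x1, y1 = video.truth.static_box
print(f"static patch mean physical salience: {phys[y0:y1, x0:x1].mean():.2f} "
      f"(frame mean {phys.mean():.3f})")
mx0, my0, mx1, my1 = (int(v) for v in video.truth.moving_track[frame])
print(f"moving patch max motion salience:   {motion[my0:my1, mx0:mx1].max():.2f} "
      f"(frame mean {motion.mean():.3f})")
print(f"global luminance of frame {frame}:      {maps[frame].global_luminance:.3f}")

summary = scene_salience_summary([m.physical_salience for m in maps])
print(f"\nper-frame physical salience, % of maximum: "
      f"min {summary.min():.1f}, max {summary.max():.1f}")
# High values inside the planted patches confirm the maps localize the
# regions a salience-driven observer would fixate.
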