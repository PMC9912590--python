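"""Generate a small synthetic cohort and look at its ground truth.

Builds 2 ASD + 2 TD participants viewing four scenes (alternating human /
non-human), each with planted salient patches, AOI masks, blinks, and a
group x category pupil effect, then prints what was planted.
"""

from gazesal import ScreenGeometry
from gazesal.synth import CohortDesign, generate_cohort

geometry = ScreenGeometry(width_px=128, height_px=96, sampling_rate_hz=120.0)
cohort = generate_cohort(CohortDesign(n_asd=2, n_td=2), seed=7, geometry=geometry)

print(cohort.participants[["participant", "group", "age", "perceptual_iq"]].round(1))
pid = cohort.participants["participant"].iloc[0]
stream, truth = cohort.streams[pid]
print(f"\n{pid}: {len(stream)} samples, {len(truth.fixations)} planted fixations")
print(f"first fixation: onset {truth.fixations[0].onset_ms:.0f} ms "
      f"at ({truth.fixations[0].cx_px:.0f}, {truth.fixations[0].cy_px:.0f}) px "
      f"targeting the {truth.fixations[0].target}")
# The planted fixation list is the ground truth the event detector is
# benchmarked against; the participant table feeds the mixed models.
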