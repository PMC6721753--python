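"""Simulate one counting-chamber well of diluted whole blood.

Draws a ground-truth particle population (Poisson loading of each class
into 0.02 uL of blood), renders it into a 5-channel fluorescence frame
stack, and writes TIFFs plus the ground-truth CSV.
"""

import dataclasses

import evcounter as ev

# quarter-size frames keep the example quick; the pipeline is agnostic
cfg = dataclasses.replace(ev.whole_blood_sample(seed=7), frames_per_well=12)
optics = ev.OpticsConfig(frame_shape=(256, 256))

particles = ev.sample_well(cfg, well_index=0, optics=optics, well_id="demo")
stack, truth = ev.render_well(particles, optics, cfg.frames_per_well, seed=7)
ev.write_well("scratch_demo_well", "demo", stack, truth, optics)

print(f"undiluted blood per well: {ev.undiluted_volume(cfg):.3f} uL")
print(f"particles drawn: {len(particles)}")
print(truth["class"].value_counts().to_string())
print(f"frame stack shape (channels, frames, rows, cols): {stack.shape}")
# Counts are Poisson draws at concentration x 0.02 uL: e.g. leukocytes at
# 4500/uL average 90 per well. The TIFFs + truth CSV land in scratch_demo_well/.
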