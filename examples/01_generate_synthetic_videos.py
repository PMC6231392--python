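"""Generate a small labelled synthetic face-video database.

Each video is a sequence of expression segments (neutral, pain, and one
other expression) rendered as schematic faces with rigid head motion,
illumination changes and sensor noise, plus ground-truth landmarks and
pose for every frame.
"""

from painface import generate_dataset

out = generate_dataset("scratch/example_db", n_videos=3, seed=42,
                       frames_per_segment=30)
manifest = (out / "manifest.csv").read_text()
print(manifest)
print("Each row is one expression segment: which video it belongs to, the")
print("expression rendered, its class label, and how many frames it spans.")
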