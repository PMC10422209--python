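"""Score held-out slices against a five-subject healthy baseline panel.

The severity score of an image is 100x the cosine similarity between its
embedding and a healthy (NC) baseline embedding, averaged over five
baseline individuals drawn from the training split. Healthy test images
score near 100; scores fall as atrophy moves the embedding away from the
healthy cluster.
"""

import numpy as np

from neuroscore import (
    EncoderConfig, PhantomConfig, TrainConfig,
    build_baseline_panel, build_encoder, generate_phantom_dataset,
    score_dataset, train,
)

images = generate_phantom_dataset(
    PhantomConfig(n_subjects_per_stage=12, images_per_subject=2,
                  image_size=32, seed=0)
)
train_images = [im for im in images if im.split == "train"]
test_images = [im for im in images if im.split == "test"]

encoder = build_encoder(EncoderConfig(feature_dim=64, projection_dim=16, seed=0))
train(encoder, train_images, TrainConfig(batch_size=16, epochs=4, seed=0))

panel = build_baseline_panel(train_images, encoder, seed=0)
print("baseline panel subjects:", panel.subject_ids)

records = score_dataset(test_images, encoder, panel)
print("\nstage   n   mean score   min      max")
for stage in ("NC", "MCI", "AD"):
    s = np.array([r.score for r in records if r.stage == stage])
    print(f"{stage:5s} {len(s):3d}   {s.mean():8.2f}   {s.min():7.2f}  {s.max():7.2f}")
# Group mean scores decrease from NC to AD: the healthy baseline is most
# similar to healthy test subjects.
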