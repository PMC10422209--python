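"""Generate a synthetic atrophy-phantom dataset and inspect its structure.

Each subject gets one latent severity s drawn from its stage interval
(NC < MCI < AD, disjoint); the phantom's dark central ventricle grows and
its bright cortical band thins as s increases. The split is by subject.
"""

import numpy as np

from neuroscore import PhantomConfig, generate_phantom_dataset

images = generate_phantom_dataset(
    PhantomConfig(n_subjects_per_stage=10, images_per_subject=2,
                  image_size=64, seed=0)
)

print(f"{len(images)} images, "
      f"{len({im.subject_id for im in images})} subjects")
for split in ("train", "test"):
    n = len({im.subject_id for im in images if im.split == split})
    print(f"  {split}: {n} subjects")

print("\nstage   mean severity   mean dark-pixel count (ventricle + background)")
for stage in ("NC", "MCI", "AD"):
    stage_images = [im for im in images if im.stage == stage]
    sev = np.mean([im.severity_s for im in stage_images])
    dark = np.mean([(im.pixels < 0.1).sum() for im in stage_images])
    print(f"{stage:5s}   {sev:10.3f}      {dark:10.1f}")

# The dark-pixel count rises with stage: the constant background plus a
# ventricle whose area grows monotonically with the latent severity.
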