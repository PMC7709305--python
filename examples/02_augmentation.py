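"""Traditional versus domain-specific augmentation of a phantom case.

Traditional augmentation flips/rotates/adds noise — easy to spot as
synthetic.  Domain-specific augmentation stays within plausible CT anatomy:
an elastic deformation (simulating a different anatomy) followed by constant
HU shifts inside the body and organ contours (simulating density variation).
"""

import numpy as np

from oarseg.augment import (DomainAugParams, TraditionalAugParams,
                            domain_specific_augment, rng_from_seed,
                            traditional_augment)
from oarseg.phantom import PhantomConfig, generate_phantom

case = generate_phantom(PhantomConfig.desk_scale(), seed=3)

trad = traditional_augment(case, TraditionalAugParams(), rng_from_seed(1))
print(f"traditional: laterality {case.laterality} -> {trad.laterality}, "
      f"mean HU shift {trad.image.voxels.mean() - case.image.voxels.mean():+.1f}")

params = DomainAugParams.for_organ("SMG")  # elastic alpha 38, sigma 3.8
dom = domain_specific_augment(case, params, rng_from_seed(1))
v0, v1 = int(case.organ_mask.sum()), int(dom.organ_mask.sum())
body_delta = np.median((dom.image.voxels - case.image.voxels)[case.body_mask > 0])
print(f"domain-specific: organ volume {v0} -> {v1} voxels "
      f"({(v1 - v0) / v0:+.1%}), body density shift {body_delta:+.1f} HU")
# The elastic field changes the organ's shape (and slightly its volume);
# the density shifts move all body/organ voxels by one random HU constant.
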