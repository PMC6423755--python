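"""Generate the synthetic study cohorts.

Emulates the study design on synthetic data: a 60-patient training cohort
(D1), a 100-patient test cohort (D2), and a demonstration TMA spot image
pair (one high-disorder recurrence-like spot, one low-disorder spot).
Writes cohort tables and feature matrices under results/data/.
"""

import sys
from pathlib import Path

import numpy as np

from ngahic import io
from ngahic.core import NuclearMask
from ngahic.simulate import (
    NEGATIVE_SPOT_KWARGS,
    POSITIVE_SPOT_KWARGS,
    CohortSimParams,
    SpotSimParams,
    generate_cohort,
    generate_spot_image,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

rng = np.random.default_rng(SEED)
seed_d1, seed_d2 = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))

d1, X1, _ = generate_cohort(CohortSimParams(n_patients=60, seed=seed_d1))
d2, X2, _ = generate_cohort(CohortSimParams(n_patients=100, seed=seed_d2))

d1.to_csv(OUT / "cohort_d1.csv")
d2.to_csv(OUT / "cohort_d2.csv")
X1.to_csv(OUT / "features_d1.csv")
X2.to_csv(OUT / "features_d2.csv")
(OUT / "seeds.txt").write_text(f"seed={SEED}\nd1={seed_d1}\nd2={seed_d2}\n")

for tag, kwargs in (("recurrence", POSITIVE_SPOT_KWARGS), ("non_recurrence", NEGATIVE_SPOT_KWARGS)):
    image, mask, _ = generate_spot_image(SpotSimParams(n_nuclei=80, canvas=512, seed=SEED, **kwargs))
    io.write_spot_image(OUT / f"demo_spot_{tag}.png", image)
    io.write_mask(OUT / f"demo_mask_{tag}.tif", NuclearMask(mask.astype(np.int32)))

print(f"D1: n={len(d1)}, recurrence={d1['recurrence'].sum()} "
      f"({100 * d1['recurrence'].mean():.1f}%)")
print(f"D2: n={len(d2)}, recurrence={d2['recurrence'].sum()} "
      f"({100 * d2['recurrence'].mean():.1f}%)")
print(f"feature matrices: {X1.shape} (D1), {X2.shape} (D2)")
print(f"demo spots written to {OUT}/demo_spot_*.png")
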