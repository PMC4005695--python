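"""Expression-noise analysis: CoV, noise differential and group contrasts.

The coefficient of variation falls with mean abundance, so gene-specific
noise is measured as the CoV minus the running-median CoV of similarly
abundant genes (the noise differential).  Splitting genes at the noise-
differential quartiles and comparing mRNA levels recovers the planted
pattern: noisy genes are transcribed less.
"""

import numpy as np

from seq2abundance import (
    mann_whitney,
    noise_differential,
    quartile_noise_groups,
)
from seq2abundance.feature_catalog import MRNA_COLUMN
from seq2abundance.synthetic_data import generate_bundle

bundle = generate_bundle(n=600, seed=2)
records = noise_differential(bundle.noise_records, window=51)
labels = quartile_noise_groups(records)

nd = np.array([r.noise_differential for r in records])
planted = set(bundle.truth.cov_law.planted_offsets)
mask = np.zeros(len(records), bool)
mask[sorted(planted)] = True
print(f"planted CoV offset: 0.30; recovered mean noise differential of "
      f"planted genes: {nd[mask].mean():.3f}")

hi, lo = labels == "high_nd", labels == "low_nd"
mrna = bundle.feature_table.data[MRNA_COLUMN].to_numpy()
u, p = mann_whitney(mrna[hi], mrna[lo])
print(f"median log10 mRNA, high-noise group: {np.median(mrna[hi]):.2f}")
print(f"median log10 mRNA, low-noise group:  {np.median(mrna[lo]):.2f}")
print(f"Mann-Whitney U = {u:.0f}, two-sided p = {p:.2e}")
# High-noise-differential genes have systematically lower mRNA: the same
# protein output from fewer transcripts means burstier expression.
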