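"""Engineered features: srf filter, ICD-10 roll-up, CCMU, windows.

Walks the individual feature operations on small hand-made inputs and
prints the numbers they produce.
"""

import numpy as np
import pandas as pd

from edlos import activity_index, encode_ccmu, recent_visit_flag, rollup_icd10, srf_score
from edlos.config import SrfParams
from edlos.features import filter_relevant_concepts

# -- srf relevance filter ------------------------------------------------
params = SrfParams()
print(f"srf cutoff at 45% prevalence threshold: {params.srf_cutoff:.3f}")
for a, c in [(55, 45), (90, 10), (50, 50), (0, 0)]:
    print(f"  srf(a={a}, c={c}) = {srf_score(a, c):.3f}")
incidence = {"balanced": (50, 50), "boundary": (55, 45), "discriminative": (90, 10)}
print("kept concepts:", sorted(filter_relevant_concepts(incidence, params)))
# Only 'discriminative' survives: scores at or below the 1.688 cutoff are
# non-relevant, including the exact boundary case (55, 45).

# -- ICD-10 roll-up ------------------------------------------------------
counts = {"M6289": 3, "M628": 1, "J189": 212, "A00": 1}
print("\nICD-10 roll-up:", rollup_icd10(counts))
# Rare M6289 rolls to M628 (pooled count 4, still rare) then to M62;
# frequent J189 and the 3-character A00 stay put.

# -- CCMU and time-window features --------------------------------------
print("\nCCMU encoding:", {c: encode_ccmu(c) for c in ["1", "3", "5", "P", "D"]})

entry = pd.Timestamp("2019-05-20 10:00")
print("recent-visit flag (prior 3 d before):",
      recent_visit_flag(entry, [entry - pd.Timedelta(days=3)]))
print("recent-visit flag (prior 8 d before):",
      recent_visit_flag(entry, [entry - pd.Timedelta(days=8)]))

ks = np.arange(100)  # prior-7-day admission counts across a toy cohort
print("activity index at k=5, 50, 95:",
      np.round(activity_index([5, 50, 95], ks), 2))
# Counts below the 1st decile clamp to 0, above the 9th decile to 1,
# and counts in between interpolate linearly.
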