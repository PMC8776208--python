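"""Turn one night of inter-beat intervals into a nightly RMSSD value.

Synthesizes a 60-minute night calibrated to an RMSSD of 40 ms, corrupts 2%
of beats with ectopic doublings, and shows that artifact screening plus
5-minute segment averaging recovers a value close to the clean target.
"""

import numpy as np

from hrvstress import flag_artifacts, process_night
from hrvstress.synthetic import simulate_ibi_night

rng = np.random.default_rng(7)
night = simulate_ibi_night(rng, target_rmssd_ms=40.0, duration_minutes=60, artifact_rate=0.02)

normal = flag_artifacts(night)
summary = process_night(night)

print(f"beats recorded:        {len(night)}")
print(f"flagged abnormal:      {int((~normal).sum())} ({100 * (~normal).mean():.1f}%)")
print(f"valid 5-min segments:  {summary.n_valid_segments}/{summary.n_total_segments}")
print(f"nightly RMSSD:         {summary.rmssd_ms:.1f} ms (target 40.0)")
print(f"lnRMSSD:               {summary.ln_rmssd:.3f}")
print()
print("RMSSD is the root mean square of successive inter-beat-interval")
print("differences; the nightly value averages the artifact-screened 5-minute")
print("segments, and its natural log (lnRMSSD) is what the analysis models.")
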