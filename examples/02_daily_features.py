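"""Build the daily table: lnRMSSD, rolling HRVsd, and shift-aware EMA days.

Constructs two weeks of nightly lnRMSSD with two missing nights, derives the
7-day rolling standard deviation (HRVsd) under the ≥3-of-7-prior-days rule,
and shows how evening and next-morning EMA responses land on the same study
day.
"""

from datetime import datetime

import numpy as np
import pandas as pd

from hrvstress import assign_ema_day, rolling_sd

dates = pd.date_range("2020-07-01", periods=14, freq="D")
ln_rmssd = pd.Series(4.0 + 0.02 * np.arange(14), index=dates)
ln_rmssd.iloc[[4, 9]] = np.nan  # two nights without a ring reading

hrv_sd = rolling_sd(ln_rmssd)
table = pd.DataFrame({"ln_rmssd": ln_rmssd.round(3), "hrv_sd": hrv_sd.round(4)})
print(table)
print()
print("hrv_sd is the sample SD of the non-missing lnRMSSD values on the 7")
print("calendar days before each date, defined once at least 3 are observed —")
print("the first defined day is therefore day 4.")
print()

evening = datetime(2020, 7, 3, 22, 15)
morning = datetime(2020, 7, 4, 9, 40)
print(f"EMA at {evening} -> study day {assign_ema_day(evening)}")
print(f"EMA at {morning} -> study day {assign_ema_day(morning)}")
print("The alcohol item stays open 19:00–15:00 so night-shift workers can")
print("answer after work; both responses above report on 2020-07-03.")
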