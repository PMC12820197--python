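"""Summarize a temperature-logger series with the three climate metrics.

Annual mean drives the favorability axis, DTR (diurnal range) the
short-term variability axis, STR (seasonal range) the climatic
variability axis.
"""

import numpy as np
import pandas as pd

from thermassembly import climate_metrics

# one synthetic year of half-hourly records: seasonal cycle + diurnal cycle
idx = pd.date_range("2022-01-01", "2022-12-31 23:30", freq="30min")
day_of_year = idx.dayofyear.to_numpy()
hour = (idx.hour + idx.minute / 60).to_numpy()
temps = (
    16.0
    + 7.0 * np.sin(2 * np.pi * (day_of_year - 110) / 365)  # seasonal swing
    + 4.0 * np.sin(2 * np.pi * (hour - 9) / 24)  # diurnal swing
)
log = pd.DataFrame({"timestamp": idx, "temp_c": temps})

m = climate_metrics(log)
print(f"annual mean  {m.annual_mean:6.2f} degC")
print(f"DTR          {m.dtr:6.2f} degC   (diurnal amplitude 4 -> range ~8)")
print(f"STR          {m.str_:6.2f} degC   (seasonal amplitude 7 plus diurnal tails)")
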