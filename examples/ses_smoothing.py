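"""The day-of-week smoothing arm on its own.

Each weekday's weekly sub-series gets a single-exponential smoother with a
grid-optimised constant; the smoother's next level is the one-week-ahead
prediction for that weekday.
"""

from ovforecast import generate, load_preset, ses_fit_panel, to_weekday_panel
from ovforecast.ses import states_to_frame

series = generate(load_preset("eov_like"))
panel, _ = to_weekday_panel(series)
states = ses_fit_panel(panel.head(43))

print(states_to_frame(states).round(3).to_string(index=False))
print("\npredictions for the next week (Mon..Sun):",
      [round(s.prediction, 1) for s in states])
print("\nA small alpha means that weekday is stable (long memory pays off);")
print("a large alpha means recent weeks dominate, tracking drift quickly.")
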