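"""Reporting conventions: percent change and unit conversion.

Takes the coefficient sets encoded in the two presets (initial level and
immediate impact per marker) and prints them the way impact results are
reported: a magnitude percentage with its direction, and hour/minute
conversions for the second-valued markers.
"""

import ambient_phenotype as ap
from ambient_phenotype.its import convert_units, percent_change

for name, preset in (("pandemic lockdown", ap.covid_preset()),
                     ("wildfire smoke", ap.smoke_preset())):
    print(f"\n{name}:")
    for marker, (b0, _, b2, _) in preset.marker_truth.items():
        pc = percent_change(b0, b2)
        if pc is None:
            print(f"  {marker:<17} baseline level is zero; percent undefined")
            continue
        pct, direction = pc
        line = f"  {marker:<17} {pct:7.2f}% {direction}"
        if marker in ("sleep_duration", "time_out"):
            line += (
                f"  ({convert_units(b0)['hours']} h -> "
                f"{convert_units(b0 + b2)['hours']} h; "
                f"{convert_units(abs(b2))['minutes']} min change)"
            )
        print(line)

print(
    "\nPercent change is 100*|immediate impact|/|initial level|; the sign is"
    "\ncarried separately because normalized markers can have negative baselines."
)
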