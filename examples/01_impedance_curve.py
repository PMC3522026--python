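"""The travel-time impedance function, evaluated at notable times.

The impedance divides a population's contribution to demand and a
physician's contribution to access: 1 inside 10 minutes (no penalty),
t/10 up to the 120-minute cutoff, and infinite beyond it, so a pair past
two hours contributes exactly nothing.
"""

from graviaccess import impedance

for t in [0, 5, 10, 20, 60, 80, 120, 121, 180]:
    f = impedance(t)
    contrib = 100.0 / f  # what a population of 100 contributes to demand
    print(f"t = {t:3d} min   f(t) = {f:6.2f}   100/f(t) = {contrib:6.2f}")

print()
print("an 80-minute trip carries", impedance(80) / impedance(20),
      "times the impedance of a 20-minute trip")
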