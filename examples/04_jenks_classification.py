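"""Jenks natural breaks on a skewed score distribution.

Access scores are typically heavy-tailed (a few very well served urban
blocks, many modest ones), which is why equal intervals or quantiles
misrepresent them and natural breaks are used for mapping.
"""

import numpy as np

from graviaccess import jenks_breaks

rng = np.random.default_rng(0)
scores = np.round(rng.lognormal(mean=-4.0, sigma=1.0, size=200), 5)

breaks = jenks_breaks(scores, k=5)
print("breaks:", [float(b) for b in breaks])

edges = [scores.min(), *breaks, scores.max()]
counts = np.histogram(scores, bins=np.array(edges) + 1e-12)[0]
prev = 0.0
for i, b in enumerate([*breaks, scores.max()]):
    n = ((scores > prev) & (scores <= b)).sum() if i else (scores <= b).sum()
    print(f"class {i + 1}: ({prev:.5f}, {b:.5f}]  {n} blocks")
    prev = b
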