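"""From TSIB to oceanic connectivity (OC) via the shortest-path network.

TSIB is normalized to relative dispersal probabilities (each directed pair's
share of the total).  Pairs without direct transport get an indirect score:
edges are weighted -ln(p), the minimum-weight path maximizes the product of
probabilities, and the product is divided by the number of intermediate
stepping-stone populations.
"""

import numpy as np
import pandas as pd

import seaflow as sf
from seaflow.matrices import DirectionalMatrix

labels = ["A", "B", "C"]
tsib = DirectionalMatrix(pd.DataFrame(
    [[0.0, 30.0, 0.0],
     [10.0, 0.0, 8.0],
     [0.0, 0.0, 0.0]], index=labels, columns=labels), kind="tsib_hours")
print("TSIB hours:\n", tsib.values)

p = sf.relative_probability(tsib)
print("\nrelative dispersal probability (off-diagonal sums to 1):\n",
      p.values.round(4))

oc = sf.network_connectivity(p)
print("\nnetwork OC (asymmetric):\n", oc.values.round(4))
print("\nA->C has no direct edge; its OC is p(A->B) * p(B->C) / 1 "
      f"= {p.values.loc['A', 'B'] * p.values.loc['B', 'C']:.4f} "
      "(one intermediate population).")

oc_sqrt = sf.network_connectivity(p, sqrt_transform=True)
print("\nsquare-root transformed (as used in the regressions):\n",
      oc_sqrt.values.round(4))
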