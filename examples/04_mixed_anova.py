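"""2x2 (group x time) mixed ANOVA with partial eta-squared and its CI.

Simulates 12 subjects per group where only the sprain-history group changes
from pre to post (a group x time interaction), runs the mixed ANOVA, and
prints F, p, partial eta-squared with its noncentral-F 95% CI and the
conventional magnitude label (0.01/0.06/0.14 = small/medium/large).
"""

import numpy as np
import pandas as pd

from coordgait import mixed_anova_2x2

rng = np.random.default_rng(3)
n = 12
pre = np.concatenate([rng.normal(212.7, 15, n), rng.normal(268.7, 15, n)])
post = pre + np.concatenate([rng.normal(22.8, 10, n), rng.normal(0.0, 10, n)])
table = pd.DataFrame(
    {
        "subject": [f"s{i}" for i in range(2 * n)],
        "group": ["RASH"] * n + ["nonRASH"] * n,
        "pre": pre,
        "post": post,
    }
)

res = mixed_anova_2x2(table)
for effect, r in res.effects.items():
    print(
        f"{effect:12s} F({r.df1},{r.df2}) = {r.F:7.3f}  p = {r.p:.4f}  "
        f"eta_p2 = {r.eta_p2:.3f} [{r.ci95[0]:.3f}, {r.ci95[1]:.3f}]  ({r.size_label})"
    )
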