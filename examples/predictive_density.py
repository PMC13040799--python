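"""Per-tip posterior predictive density curves.

After a fit, each tip's predictive density is an exact mixture of normals:
one component per resampled posterior draw, with mean and variance obtained
by composing the regime transition coefficients along the root-to-tip path.
The script prints, for a few tips, the predictive mean and the observed
value, and verifies each curve integrates to one.
"""

import numpy as np

from mgpm import ModelSpec, pmc_sample, predictive_density_at_tips, simulate_tips
from mgpm.priors import diffuse_prior
from mgpm.treeio import random_clade_painting, random_ultrametric_tree

tree = random_ultrametric_tree(30, seed=2)
painting = random_clade_painting(tree, 2, seed=9, min_frac=0.3, max_frac=0.6)
spec = ModelSpec(tree, painting, ("OU", "OU"))
truth = spec.pack(0.0, [(2.0, 2.0, 1.0), (5.0, 0.0, 0.5)])
x = simulate_tips(spec, truth, seed=4)

sample = pmc_sample(spec, diffuse_prior(spec), x, S=2000, seed=8, n_starts=4)

grid = np.linspace(-4, 6, 800)
curves = predictive_density_at_tips(sample, grid, S=500, seed=12)

# a few tips from each regime (tips on an ultrametric tree that share a
# regime along their whole path share the same predictive marginal)
tips = list(tree.tips)
shown = 0
for k in range(painting.n_regimes):
    in_regime = [v for v in painting.edges_in(k) if v in tips][:3]
    for v in in_regime:
        i = tips.index(v)
        label = tree.labels[v]
        mean = np.trapezoid(curves[i] * grid, grid)
        total = np.trapezoid(curves[i], grid)
        print(f"tip {label} ({painting.names[k]}): predictive mean {mean:+.3f}, "
              f"observed {x[label]:+.3f}, integral {total:.4f}")
        shown += 1
print(
    "\nEach curve integrates to ~1; tips in the strongly pulled regime"
    "\nconcentrate near that regime's optimum."
)
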