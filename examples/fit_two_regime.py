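"""Fit a two-regime OU model to simulated traits and summarize the posterior.

Builds a 50-tip unit-height Yule tree, paints a large clade as a second
regime, simulates tip data from known parameters, and runs the
Laplace-initialized PMC sampler.  The printed table gives, per parameter,
the posterior mean, sd, Monte Carlo standard error, and the 2.5/50/97.5%
quantiles; compare the medians with the simulation truth.
"""

import numpy as np

from mgpm import ModelSpec, pmc_sample, simulate_tips, summarize
from mgpm.priors import diffuse_prior
from mgpm.treeio import random_clade_painting, random_ultrametric_tree

tree = random_ultrametric_tree(50, seed=7)
painting = random_clade_painting(tree, 2, seed=3, min_frac=0.3, max_frac=0.6)
spec = ModelSpec(tree, painting, ("OU", "OU"))

truth = spec.pack(0.0, [(2.0, 2.0, 1.0), (5.0, 0.0, 0.5)])
print("truth:", dict(zip(spec.param_names, truth.tolist())))

x = simulate_tips(spec, truth, seed=11)
sample = pmc_sample(spec, diffuse_prior(spec), x, S=4000, seed=42, n_starts=6)

table = summarize(sample)
print(table.round(3).to_string(index=False))
print(f"stage-1 ESS: {sample.diagnostics['ess_stage1']:.0f}; "
      f"move acceptance: {sample.diagnostics['acceptance_rate']:.2f}")
print(
    "\nThe optima (theta) and diffusions (sigma) are typically recovered"
    "\nnear truth; the rates (alpha) and the root state X0 carry the most"
    "\nposterior uncertainty, as expected on a single short tree."
)
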