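"""Simulate co-evolved interacting homolog pairs for a synthetic family.

Builds a small template family with known interface contacts, runs the
mutation + stochastic-selection sampler, and prints how selection pressure
and contact coupling show up in the samples.
"""

import numpy as np

from coevnet import (
    GeneratorSpec,
    MCMCParams,
    generate_family,
    joint_fitness,
    mutual_information,
    run_mcmc,
)

spec = GeneratorSpec(
    n_cols_a=20, n_cols_b=20, n_contacts=5, coupling_strength=0.9,
    n_seed_pairs=1, rng_seed=0,
)
family, truth = generate_family(spec)
print(f"family: {spec.n_cols_a}+{spec.n_cols_b} columns, contacts {truth.contacts}")

params = MCMCParams(n_samples_single_seed=500, burn_in=500, thinning=10, rng_seed=0)
samples = run_mcmc(family, params)
print(
    f"generated {len(samples.samples)} sample pairs, "
    f"acceptance rate {samples.acceptance_rate:.2f}, converged={samples.converged}"
)

seed_fitness = joint_fitness(family.seed_pairs[0], family.profile_a, family.profile_b)
mean_fitness = np.mean(
    [joint_fitness(p, family.profile_a, family.profile_b) for p in samples.samples]
)
# the chain should hold fitness near the seed's profile score, not drift to noise
print(f"seed fitness {seed_fitness:.1f} bits; mean sample fitness {mean_fitness:.1f} bits")

i, j = truth.contacts[0]
mi = mutual_information(samples, ("A", i), ("B", j), pseudocount=0.01)
print(f"MI at contact ({i},{j}): {mi:.2f} bits — inter-protein coupling carried by the sampler")
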