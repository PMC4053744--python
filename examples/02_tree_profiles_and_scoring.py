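"""Learn positive/negative tree profiles and score candidate interfaces.

The positive tree is learned from simulated interacting pairs, the negative
tree from the same samples with partner assignments deranged (background
correlations only).  A query interface is scored by its log-likelihood under
each tree; the contrast L+ - L- is the co-evolution signal.
"""

import numpy as np

from coevnet import (
    GeneratorSpec,
    InterfaceAssignment,
    MCMCParams,
    build_profile_pair,
    draw_pair,
    generate_family,
    score_interface,
)

spec = GeneratorSpec(rng_seed=1)  # 30+30 columns, 8 contacts, coupling 0.9
family, truth = generate_family(spec)
profile_pair = build_profile_pair(
    family, MCMCParams(n_samples_per_seed=500, rng_seed=1)
)
print(
    f"learned trees over {len(profile_pair.positive.nodes)} interface nodes; "
    f"positive edges: {len(profile_pair.positive.edges)}"
)

rng = np.random.default_rng(2)
for coupled, label in ((True, "co-evolved pair   "), (False, "independent pair  ")):
    diffs = []
    for _ in range(50):
        pair = draw_pair(truth, coupled=coupled, rng=rng)
        assignment = InterfaceAssignment.from_pair(pair, family.contact_map)
        l_plus, l_minus = score_interface(assignment, profile_pair)
        diffs.append(l_plus - l_minus)
    print(
        f"{label} mean L+ - L- = {np.mean(diffs):+6.2f} bits "
        f"(positive favors genuinely co-evolved interfaces)"
    )
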