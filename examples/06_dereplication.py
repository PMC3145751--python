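"""Dereplicate an environmental sequence pool at 98% identity.

The pool contains, per reference, copies at 100%, 99% and 90% target
identity.  Greedy scanning keeps one representative per >= 98% cluster:
exact and 99% copies collapse onto the first copy seen, 90% variants are
retained as distinct entries.
"""

import numpy as np

import phylorobust as pr

rng = np.random.default_rng(5)
refs = [(f"ref{i}", "".join(rng.choice(list("ACGT"), 400))) for i in range(3)]
pool = pr.make_environmental_pool(refs, identity_targets=(1.0, 0.99, 0.90), seed=5)
print(f"pool size: {len(pool)} (3 references x 3 identity targets)")

retained, cluster = pr.dereplicate(pool, threshold=0.98)
print(f"retained after 98% dereplication: {len(retained)}")
for label, _ in retained:
    absorbed = [l for l, rep in cluster.items() if rep == label and l != label]
    print(f"  {label}  absorbs {absorbed if absorbed else 'nothing'}")
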