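"""The ASK-probing baseline on the same worked query and layout.

An index-free federator must probe every (pattern, endpoint) pair with a
SPARQL ASK: 6 patterns x 17 endpoints = 102 requests on a cold cache, and
it over-selects wherever a predicate is stored at many endpoints.
"""

import tcgafed as tf
from tcgafed.selection import AskCache

fx = tf.generate(tf.deployment_config(seed=1))
pool = tf.spawn_endpoints(fx)
text, _ = tf.worked_example_query(fx)
bgp = tf.parse_query(text).bgp

cache = AskCache()
sel, n_cold = tf.ask_baseline(bgp, fx.index, pool.ask, cache)
_, n_warm = tf.ask_baseline(bgp, fx.index, pool.ask, cache)

print(f"cold-cache ASK requests: {n_cold}  (6 patterns x 17 endpoints)")
print(f"warm-cache ASK requests: {n_warm}")
for tp in bgp.patterns:
    print(f"pattern {tp.index}: {len(sel.sources(tp.index)):2d} sources")
print(f"\nASK-baseline tpws: {tf.tpws_count(sel)} vs join-aware 6")
# The tcga:result pattern matches all 17 endpoints and the barcode pattern
# the 3 endpoints (one per colour) replicating the patient — data-exact per
# pattern, but blind to the joins that make most of those sources useless.
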