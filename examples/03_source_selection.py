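"""Join-aware source selection on the 17-endpoint deployment layout.

The worked query asks for one patient's copy-number records. The barcode's
TSS resolves the tumour, and the record star's seq_mean predicate (unique
to blue) colours every pattern blue through the star/path joins — so each
of the six patterns needs exactly one endpoint.
"""

import tcgafed as tf
from tcgafed.selection import SelectionContext

fx = tf.generate(tf.deployment_config(seed=1))
pool = tf.spawn_endpoints(fx)
text, patient = tf.worked_example_query(fx)
print(text)
print(f"\npatient {patient.barcode} (TSS {patient.tss} -> {patient.tumour})\n")

bgp = tf.parse_query(text).bgp
sel = tf.select_sources(bgp, SelectionContext(fx.index, fx.tss_table),
                        ask=pool.ask)
for tp in bgp.patterns:
    urls = [e.url for e in sel.sources(tp.index)]
    print(f"pattern {tp.index}: {len(urls)} source(s) -> {urls}")
print(f"\ntriple-pattern-wise source count: {tf.tpws_count(sel)} "
      f"out of {6 * len(fx.index.endpoints)} pattern-endpoint pairs")
# All six patterns collapse onto the single blue endpoint holding the
# patient's tumour: the whole query ships as one remote sub-query.
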