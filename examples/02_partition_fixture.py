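"""Distribute a generated dataset across colour-category endpoints.

Ten tumour types, 25 patients, 2 blue / 3 pink / 5 green endpoints: every
tumour is stored once per colour, result triples land at the endpoint
matching their colour and tumour, and each patient's descriptive triples
are replicated to one endpoint of every colour.
"""

import tcgafed as tf

fx = tf.generate(tf.benchmark_config(seed=1))

print(f"{len(fx.patients)} patients over {len(fx.tumours)} tumour types, "
      f"{len(fx.union_dump)} triples total\n")
for ep in fx.index.endpoints:
    tumours = ",".join(sorted(ep.tumours))
    print(f"{ep.url:22s} {ep.colour.value:5s} {len(fx.dumps[ep.url]):5d} "
          f"triples  tumours: {tumours}")
print()
print("The green endpoints hold only methylation results, pink only exon")
print("expression, blue the remaining result kinds plus clinical data;")
print("per-endpoint sizes follow the tumour ranges of the layout.")
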