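"""Refine a raw level-3 methylation table and convert it to N3.

The refiner keeps only the analysis-relevant columns (chromosome, position,
beta_value) and skips any row whose selected field carries a missing-value
token; the RDFizer then mints one result resource per surviving row.
"""

import tcgafed as tf
from tcgafed.rdfizer import RawTable, rdfize_raw

RAW = """\
probe_name\tbeta_value\tgene_symbol\tchromosome\tposition
cg00000292\t0.5120\tATP2A1\tchr16\t28890100
cg00002426\tNA\tSLMAP\tchr3\t57743543
cg00003994\t0.8921\tMEOX2\tchr7\t15725862
"""

raw = RawTable.from_tsv(RAW, "dna-methylation")
barcode = tf.parse_patient_barcode("TCGA-A2-A0CX")
refined = tf.refine(raw, tf.default_field_map())
dump = rdfize_raw(raw, barcode)

print(f"raw rows: {len(raw.rows)}, refined rows: {len(refined.rows)} "
      "(the NA row was skipped)")
print(f"triples emitted: {len(dump)}  "
      "(patient type+barcode, then per row: link + type + 3 fields)")
print()
print(dump.to_n3())
# Each d<i> resource is one methylation measurement of patient TCGA-A2-A0CX;
# the 'd' code marks DNA methylation, which routes to the green category.
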