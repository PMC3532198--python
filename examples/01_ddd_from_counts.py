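"""Digital differential display on a hand-sized pair of EST pools.

Builds two tiny cDNA libraries, pools them, and prints each gene's
transcript frequencies, signed fold change, and Fisher exact p-value.
A fold of "+4" means the gene's EST frequency is 4x higher in the test
pool (pool A here); "+"/"-" alone mark genes seen in only one pool.
"""

import pandas as pd

from dddkit import LibraryTable, PoolManifest, run_ddd

frame = pd.DataFrame(
    [("normal_lung", "lung", "reference", g, c) for g, c in
     [("LTF", 224), ("GAPDH", 10), ("SFTPA1", 4), ("FTL", 1)]]
    + [("other_tissues", "mixed", "query", g, c) for g, c in
       [("LTF", 18), ("GAPDH", 100), ("FTL", 11)]],
    columns=["library_id", "tissue", "condition", "gene_id", "est_count"])
table = LibraryTable(frame=frame, totals={"normal_lung": 10_000,
                                          "other_tissues": 10_000})
manifest = PoolManifest(members={"A": {"normal_lung"},
                                 "B": {"other_tissues"}},
                        roles={"A": "reference", "B": "query"},
                        test_pool="A")

records = run_ddd(table, manifest, min_fold=2.0)
print(f"{'gene':<8} {'freq_A':>8} {'freq_B':>8} {'fold':>8} {'p':>10}")
for r in records:
    print(f"{r.gene_id:<8} {r.freq_a:>8.4f} {r.freq_b:>8.4f} "
          f"{str(r.fold):>8} {r.p_value:>10.3g}")
print("\nGenes with |fold| >= 2 survive; the sign follows the test pool "
      "(A, normal lung).")
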