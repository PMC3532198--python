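"""Subtractive narrowing of a candidate list, with provenance.

Starts from 76 shared hits, removes an 18-gene pan-cancer exclusion
list, then collapses identifiers through a many-to-one mapping.  The
provenance log shows the arithmetic of every step.
"""

from dddkit import CandidateSet, exclude_genes, map_identifiers

candidates = CandidateSet(ids=[f"Hs.{i:03d}" for i in range(76)])
exclusion = [f"Hs.{i:03d}" for i in range(18)]  # pan-cancer genes

narrowed = exclude_genes(candidates, exclusion)
mapping = {f"Hs.{i:03d}": f"GENE{i // 2:03d}" for i in range(76)}
canonical = map_identifiers(narrowed, mapping)

for step in canonical.log:
    print(f"{step.step:<20} {step.n_before:>4} -> {step.n_after:>4} "
          f"(removed {step.n_removed})")
print(f"\nFinal candidate list: {len(canonical)} canonical ids "
      f"(duplicates collapsed by the 2-to-1 mapping).")
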