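"""Wang semantic similarity on a toy ontology.

Builds a five-term DAG, shows the S-value table of a leaf (how much
each ancestor contributes, decaying by 0.8 per is_a edge), then scores
term pairs and two annotated genes with the best-match average.
"""

import networkx as nx

from dddkit import GeneAnnotation, s_values, term_similarity, gene_similarity
from dddkit.io_formats import OntologyGraph

g = nx.DiGraph()
for t in ["root", "membrane", "organelle", "vesicle", "lysosome"]:
    g.add_node(t, name=t, namespace="CC")
g.add_edge("membrane", "root", relation="is_a")
g.add_edge("organelle", "root", relation="is_a")
g.add_edge("vesicle", "organelle", relation="is_a")
g.add_edge("lysosome", "organelle", relation="is_a")
g.add_edge("lysosome", "membrane", relation="part_of")
ontology = OntologyGraph(graph=g)

table = s_values("lysosome", ontology)
print("S-values anchored at 'lysosome':")
for term, s in sorted(table.s.items(), key=lambda kv: -kv[1]):
    print(f"  {term:<10} {s:.3f}")
print(f"  SV = {table.sv:.3f}")

print(f"\nSim(lysosome, vesicle) = "
      f"{term_similarity('lysosome', 'vesicle', ontology):.4f}")

ann = GeneAnnotation(annotations={
    "geneX": {"CC": frozenset({"lysosome"})},
    "geneY": {"CC": frozenset({"lysosome", "vesicle"})}})
print(f"SIM(geneX, geneY)      = "
      f"{gene_similarity('geneX', 'geneY', 'CC', ann, ontology):.4f}")
print("\nThe gene score averages each term's best match in the other "
      "gene's set; shared terms contribute 1.")
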