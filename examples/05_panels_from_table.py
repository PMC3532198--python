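"""Biomarker panels from the packaged lung-cancer fixture.

Loads the packaged 38-gene biomarker table (four panels derived from
clusters of a GO-similarity dendrogram), rebuilds the panel objects,
and tallies expression directions per panel in the disease contrast.
"""

from dddkit import count_direction, load_biomarker_table, panels_from_biomarker_table

panels = panels_from_biomarker_table(load_biomarker_table())
print(f"{len(panels)} panels, {sum(len(p) for p in panels)} biomarkers\n")
for panel in panels:
    up, down, xup, xdown = count_direction(panel, "ddd2")
    print(f"panel {panel.index} ({panel.label}): {len(panel)} genes")
    print(f"   disease contrast: {up} up, {down} down, "
          f"{xup} exclusive-up, {xdown} exclusive-down")
print("\n'exclusive' genes were observed in only one pool, so their "
      "fold magnitude is undefined (printed as bare +/-).")
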