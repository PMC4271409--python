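"""Render two conflicting trees face to face with agreement shading.

Tips outside the maximum agreement subtree are drawn in light grey so the
shared structure stands out; coloured tips keep their colour only when
they are part of the consensus.
"""

from treebench import RenderSpec, mast, parse_newick, render_pair, set_color

t1 = parse_newick("(((A,B),C),((D,E),X));")
t2 = parse_newick("(((A,C),B),((D,E),Y));")
t1, t2 = set_color([t1, t2], {"D", "E"}, "#d62728")

agreement = mast(t1, t2)
spec = RenderSpec(orientation="face_to_face")
svg = render_pair(t1, t2, spec, agreement=agreement)

with open("agreement.svg", "w") as fh:
    fh.write(svg)
print(f"agreement taxa: {sorted(agreement.mast_taxa)}")
print(f"wrote agreement.svg ({len(svg)} bytes, "
      f"{svg.count('<text')} tip labels)")
# D and E stay red (in the consensus); the conflicting B/C tip and the
# tree-specific X and Y tips are shaded grey in the picture.
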