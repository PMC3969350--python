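"""Choose modeling templates for a target sequence from a bootstrap tree.

The rules mirror homology-modeling practice for highly similar peptide
families: a well-supported sister of known structure is used alone; a
weakly supported one is paired with the next-nearest known structure; a
two-leaf known sister clade is always taken whole.
"""

from cyclodesc.template_select import SupportTree, select_templates

cases = [
    ("((target,kB1)72,(cyO1,x)80);", "single template, support 72% > 50%"),
    ("((target,kB1)41,(cyO1,x)80);", "support 41% <= 50%: add nearest known"),
    ("((target,(kB2,varvF)18)90,x);", "known two-leaf sister clade: both, any support"),
]
known = {"kB1", "cyO1", "kB2", "varvF"}

for newick, why in cases:
    tree = SupportTree.from_newick(newick, known=known)
    picked = select_templates(tree, "target", seed=0)
    print(f"{newick}\n  -> templates {picked}   ({why})\n")
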