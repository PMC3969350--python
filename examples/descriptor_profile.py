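"""Compute the five surface descriptors and the per-loop lipophilicity
profile of a cyclic cystine-knot toy peptide.

A Möbius-like toy is built with its aromatic/aliphatic cluster in loop 5.
The descriptors quantify how much lipophilic and positively charged
surface the peptide exposes (L_S, L_S*, E_S) and how asymmetrically those
surfaces are distributed (L_M, E_M) — the properties that govern how such
peptides dock onto membranes.
"""

from cyclodesc import assign_loops, compute_descriptors, load_default_scale
from cyclodesc.descriptors import loop_lipophilicity_profile, residue_lipophilicity
from cyclodesc.fixtures import make_cck_toy
from cyclodesc.surface import shrake_rupley

scale = load_default_scale()
pep = make_cck_toy(
    [["GLU", "THR"], ["ASN"], ["SER", "LYS"], ["GLY"],
     ["TRP", "ILE", "PRO"], ["GLY", "ASN"]],
    label="mobius-toy",
)
assign_loops(pep, anchor=0)

d = compute_descriptors(pep, scale)
print(f"peptide {d.label}")
print(f"  L_S  = {d.L_S:+.4f}   (signed total lipophilicity)")
print(f"  L_S* = {d.L_S_star:.4f}   (lipophilicity of the lipid-facing side)")
print(f"  L_M  = {d.L_M:.4f}   (lipophilic moment, asymmetry of L)")
print(f"  E_S  = {d.E_S:.2f} A^2 (positively charged HBD surface)")
print(f"  E_M  = {d.E_M:.2f} A   (HBD amphipathic moment)")

sasa, _ = shrake_rupley(pep)
profile = loop_lipophilicity_profile(pep, residue_lipophilicity(pep, scale, sasa))
print("per-loop L_S (loop 5 carries the lipophilic patch):")
for loop_id in range(1, 7):
    print(f"  loop {loop_id}: {profile[loop_id]:+.4f}")
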