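"""Locate classic casein-derived opioid peptides in the reference caseins.

Maps four well-known opioid sequences onto the bundled mature bovine casein
chains and prints their 1-based coordinates.  Beta-casomorphin-7 should land
at beta-casein 60-66, neocasomorphin-6 at 114-119, and the alpha-casomorphin
RYLGYLE at alpha-s1-casein 90-96.
"""

from pepdigest import bundled_caseins, map_peptide

peptides = ["YPFPGPI", "YPVEPF", "SLVYPFPGPI", "RYLGYLE", "YFYPEL"]
proteins = bundled_caseins()

for peptide in peptides:
    for protein_id, start, end in map_peptide(peptide, proteins):
        print(f"{peptide:>11s} -> {protein_id}  {start}-{end}")

# Each line gives the parent casein and the inclusive mature-chain span of
# the peptide; a unique span means the identification is positionally
# unambiguous.
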