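"""Terminal-residue logo content and top C-terminal tripeptides.

Builds the 20x6 terminal probability matrix (positions N1-N3 and C-3..C-1)
for each substrate of a synthetic study and prints the most probable residue
per position plus the three most frequent C-terminal tripeptides.
"""

from pepdigest import simulate_study, terminal_logo, top_terminal_kmer

table, _, _ = simulate_study(seed=1)

for substrate, group in table.groupby("substrate"):
    peptides = group["sequence"].tolist()
    logo = terminal_logo(peptides, min_length=5)
    tops = {pos: logo.probs[pos].idxmax() for pos in logo.probs.columns}
    best = {pos: logo.probs[pos].max() for pos in logo.probs.columns}
    print(f"{substrate} ({logo.n_peptides} peptides, "
          f"{logo.n_excluded_short} below length 5):")
    print("  most probable terminal residues: "
          + "  ".join(f"{pos}={tops[pos]} ({best[pos]:.2f})" for pos in logo.probs.columns))
    kmers = top_terminal_kmer(peptides, end="C", k=3)[:3]
    print("  top C-terminal tripeptides: "
          + ", ".join(f"{kmer} x{count}" for kmer, count in kmers))

# Column probabilities summarise apparent cleavage preference; the dominant
# C-terminal residues reflect the P1 specificity of the digesting proteases.
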