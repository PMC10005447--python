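"""Residue coverage profiles and peptide size distributions of a synthetic
two-substrate study.

Simulates duodenal peptidomes for intact casein and a casein hydrolysate
(6 animals x 10 time points), maps all peptides, and prints (a) per-time
unique/common peptide counts, (b) the share of the beta-casein coverage mass
sitting on the digestion-resistant C-terminal domain 193-209, and (c) the
fraction of peptides longer than 10 residues per substrate.
"""

from pepdigest import (
    PeptideObservation,
    bundled_caseins,
    count_summary,
    fraction_longer_than,
    map_observations,
    residue_profile,
    simulate_study,
)

table, _, _ = simulate_study(seed=1)
observations = [PeptideObservation(**row) for row in table.to_dict("records")]
mapped, report = map_observations(observations, bundled_caseins())
print(f"mapped {report.n_mapped_unique} peptides uniquely, "
      f"{report.n_ambiguous} ambiguous, {report.n_unmapped} unmapped")

beta = next(p for p in bundled_caseins() if p.protein_id == "CASB_BOVIN")
for substrate in ("casein", "hydrolysate"):
    subset = [o for o in mapped if o.substrate == substrate]
    summary = count_summary(subset, n_animals=6)
    totals = [t for t, _ in summary.per_time.values()]
    values = residue_profile(subset, beta, "occurrence_count").values
    cterm_share = values[192:209].sum() / values.sum()
    long_frac = fraction_longer_than(subset, 10)
    print(f"{substrate:>12s}: per-time unique peptides {min(totals)}-{max(totals)} "
          f"(column total {summary.column_totals[0]}), "
          f"beta-CN 193-209 mass share {cterm_share:.3f}, "
          f"fraction >10 aa {long_frac:.3f}")

# The casein digest concentrates coverage on the protected C-terminal
# domain and keeps a much larger share of long peptides than the
# pre-hydrolysed substrate.
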