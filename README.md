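# pepdigest

Peptidomic analysis of gastrointestinal protein digests, built around the
comparison of duodenal peptidomes after intake of intact micellar casein
("slow" protein) versus a pepsin casein hydrolysate ("fast" protein) in a
cannulated-pig model of human digestion. The package takes identified
peptide tables (sequence, MS intensity, substrate, time point, animal) and
turns them into the quantities such a study reports: peptide-to-protein
coverage maps, per-residue intensity and occurrence profiles, size
distributions, terminal cleavage logos, count summaries, multivariate
discrimination of substrates over time, and plasma amino-acid time-course
statistics. It is aimed at food-protein and digestion researchers who work
with MS/MS peptide identifications rather than raw spectra.

## What it computes

* **Mapping.** Identified peptides are located by exact substring match in
  mature reference proteins (bundled: the four major bovine caseins, signal
  peptides removed, so β-casomorphin-7 = β-casein ⁶⁰YPFPGPI⁶⁶). Ambiguous
  and unmapped peptides are accounted for explicitly.
* **Residue profiles.** For protein residue *p* and sample *s*,
  `I(p, s) = Σ_k 1[start_k ≤ p ≤ end_k] · x_k`, the sum of intensities
  `x_k` of all peptides overlapping *p* (occurrence mode sets `x_k = 1`).
* **Terminal logos.** The 20×6 column-stochastic matrix of amino-acid
  probabilities at peptide positions N1–N3 and C−3–C−1; for a length-5
  peptide the middle residue contributes to both N3 and C−3.
* **Multivariate.** PCA by SVD of the samples × residues matrix (columns
  mean-centred; `explained_ratio_j = s_j² / Σ s²`), and Ward/Euclidean
  agglomerative clustering of samples in peptide-intensity space
  (log10(1+x)-transformed), restricted to peptides present in ≥2 time
  points.
* **Plasma statistics.** Per analyte, a balanced two-way fixed-effects
  ANOVA (substrate × time) followed by per-time t contrasts on the pooled
  error with Bonferroni adjustment over the sampled time points.
* **Synthetic data.** A stochastic in-silico digestion model (pepsin-like
  P1 preferences, proline suppression, protected regions such as β-casein
  193–209, hydrolysis extent controlling fragment sizes) plus a plasma
  generator — every pipeline stage is testable without any external data.

## Worked example

```python
from pepdigest import bundled_caseins, map_peptide
for pep in ["YPFPGPI", "YPVEPF", "RYLGYLE"]:
    print(pep, map_peptide(pep, bundled_caseins()))
```

prints the literature coordinates of the casein opioid peptides:

```
YPFPGPI [('CASB_BOVIN', 60, 66)]
YPVEPF [('CASB_BOVIN', 114, 119)]
RYLGYLE [('CASA1_BOVIN', 90, 96)]
```

A full synthetic study (`python examples/02_residue_profiles.py`) prints:

```
mapped 19673 peptides uniquely, 127 ambiguous, 0 unmapped
      casein: per-time unique peptides 439-464 (column total 4522), beta-CN 193-209 mass share 0.154, fraction >10 aa 0.239
 hydrolysate: per-time unique peptides 344-362 (column total 3542), beta-CN 193-209 mass share 0.106, fraction >10 aa 0.100
```

i.e. a few hundred unique peptides per time point per substrate, with the
casein digest keeping far more long peptides (24% vs 10% above 10 residues)
and concentrating coverage on the digestion-resistant β-casein C-terminal
domain. `examples/04_multivariate.py` shows PC1 separating the substrates
(casein scores all positive, hydrolysate all negative) and a 2-cluster cut
of the dendrogram recovering the substrate labels exactly;
`examples/05_plasma_anova.py` shows the planted early plasma differences
detected at early time points only, with a null analyte staying silent.

The `pepdigest` console script exposes the same stages as subcommands
(`simulate`, `map`, `profile`, `sizes`, `logo`, `counts`, `pca`, `cluster`,
`plasma`, `all`), writing TSV/Newick/JSON artifacts plus a manifest with
checksums; see `pepdigest --help`.

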