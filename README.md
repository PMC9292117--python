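# ndrchip

Occupancy analysis of ChIP-seq and MNase ChIP-seq data at yeast promoter
nucleosome-depleted regions (NDRs): how chromatin remodelers shape
transcription-activator binding, promoter nucleosome eviction, and TBP
recruitment during preinitiation-complex assembly.

The package is written for regulatory-genomics analyses of the kind done on
amino-acid-starvation induction in *S. cerevisiae*: an activator (Gcn4) binds
consensus motifs located in promoter NDRs ("5' sites") or inside coding
sequences ("ORF sites"); remodeler mutants (SWI/SNF, RSC, Ino80C catalytic
subunits) change activator occupancy, histone H3 occupancy, and TBP/Pol II
recruitment in a site-class-specific way.  Because the interesting questions
are comparative — mutant vs wild type, induced vs uninduced, tagged vs
untagged — the package is built around normalized per-bp occupancy tracks and
window statistics, and it ships a fragment-level simulator with planted
ground truth so that every stage of the pipeline can be validated end to end.

## What it computes

* **Coverage tracks** — the occupancy at base pair *b* is the number of
  sequenced fragments overlapping *b*; each chromosome is normalized so its
  mean occupancy per nucleotide is 1, making samples comparable.
* **Dyad densities** — midpoints of nucleosome-size MNase fragments
  (125–175 bp) estimate nucleosome dyad positions; averaged profiles are
  smoothed with a 31 bp moving average.
* **Background-corrected occupancies** — normalized epitope-tagged remodeler
  signal minus the matched untagged-strain signal (signed values kept).
* **Anchor-aligned matrices and profiles** — site × relative-position
  matrices around motif centers, TBP summits or TSSs, with strand
  orientation, NaN edge handling, stable sorting and difference maps.
* **Window quantification** — occupancy per nucleotide over peak intervals,
  anchor ± 100 bp windows, or CDSs; log2 columns with a shared pseudocount.
* **Set constructions** — features ranked by mutant/WT fold change and split
  into outer/middle quartile sets (ceil(n/4) / remainder / ceil(n/4), i.e.
  30/57/30 at n = 117), expression deciles, High/Low halves, and
  nearest-summit-to-TSS assignment.
* **Statistics** — Mann–Whitney–Wilcoxon comparisons with the usual star
  ladder (\*\*\*\* ≤ 1e-4 … \* ≤ 0.05), Pearson correlations, notched-box
  summaries (notch = 1.57·IQR/√n), and sector (quadrant) scatter
  classification.
* **Synthetic data** — a two-chromosome genome tiled with gene units
  (120 bp NDRs, −1/+1 dyads at ±133 bp, 165 bp genic spacing), planted
  binding strengths β per site class, eviction effects ε, TBP kernels
  +130 bp downstream of 5' motifs, sonicated (300–500 bp) and MNase
  fragment-length models, and a recovery harness scoring the pipeline
  against exact expectations computed from the enrichment landscapes.

## Worked example

```python
from ndrchip.pipeline import simulate_and_run

out = simulate_and_run(seed=1)          # 117 5' sites, 5e5 fragments x 2 reps
print(out["sets"].sizes())
print(out["report"].to_frame()[["name", "value", "passed"]])
```

```
{'Set_1': 30, 'Set_2': 57, 'Set_3': 30}
                                name         value  passed
0  induction_log2fc_median_abs_error  2.099942e-02    True
1               h3_eviction_defect_p  6.865606e-40    True
2        dyad_peak_position_error_bp  1.000000e+00    True
3           tbp_peak_offset_error_bp  0.000000e+00    True
```

Reading: the 117 simulated 5' sites, ranked by their activator fold change in
the Snf2/Sth1 double mutant vs WT, partition into quartile sets of 30/57/30.
The pipeline re-estimates each site's planted log2 induction to a median
absolute error of 0.02; H3 occupancy at the motifs is significantly elevated
in the eviction-defective double mutant (Mann–Whitney p ≈ 7e-40 across 117
sites); the −1/+1 nucleosome dyad peaks are recovered within 1 bp of the
planted ±133 bp, and the TBP summit profile peaks exactly at the planted
+130 bp downstream offset.

The numbered drivers under `analysis/` run the same machinery step by step at
reduced depth (1e5 fragments per sample) and write their tables under
`results/` — for example `analysis/04_quantify_and_partition.py` prints the
cross-table of recovered quartile sets against the planted
remodeler-dependence classes (partition purity 0.93), and
`analysis/05_set_statistics.py` prints the per-set Mann–Whitney table in
which the double mutant loses binding in Sets 1–2 (\*\*\*\*) while the
snf2-null strain gains binding in Set 3 (\*\*\*\*).

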