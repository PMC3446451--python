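# seroarray

Autoantibody profiling of duplicate-spotted protein microarrays, built for
studies that compare antibody reactivities between paired body fluids — the
motivating case is juvenile idiopathic arthritis (JIA), where plasma (PL)
and synovial fluid (SF) from the same patients are screened against 768
in-situ-expressed protein antigens (NAPPA-style arrays) to ask whether
circulating antibodies mirror those in the inflamed joint.

The package takes spot-level quantification tables (one row per printed
spot) and carries them through:

1. **Normalization** — the normalized volume of each spot is
   `log10(max(V - B, floor))`, where `B` is the array background estimated
   as the first quartile of the nonspot signals; the two printed replicates
   of each antigen are then collapsed by their mean log value.
2. **Reproducibility QC** — per-array Pearson correlation `r` between
   duplicate spots (intra-array precision) and per-patient correlation
   between the PL and SF reactivity vectors.
3. **Differential classification** — per antigen, the PL/SF geometric-mean
   fold change `R = 10^(mean_PL - mean_SF)` is binned: *PL-higher* if
   `R > 1.45`, *SF-higher* if `R < 1/1.45`, *similar* if within ±10% of
   unity, otherwise unclassified. This is a fold-change filter, not a
   hypothesis test. Robust per-patient outlier antibodies
   (`|PL - SF| > 3` scaled MADs) are flagged alongside.
4. **UPGMA clustering** — from-scratch agglomerative clustering
   (unweighted pair-group method with arithmetic mean) on Euclidean
   distances over antigens and over samples, with deterministic
   tie-breaking, seriation, tree cuts and Newick/heatmap export.
5. **ELISA verification** — duplicate-mean absorbances and a two-sided
   paired Student t-test between fluids.

Because raw patient scans for such studies are rarely deposited, the
package includes a first-class synthetic-cohort generator
(`seroarray.synthetic`) whose defaults encode the study conditions: 768
duplicate-spotted antigens, 10 patients × 2 fluids, duplicate-spot
correlation 0.98, inter-fluid correlation 0.96, planted differential
antigens (29 PL-higher / 1 SF-higher / 6 near-equal at 1.8-fold) and a 6/4
patient split in global antibody level. Every pipeline stage is tested
against this generator's ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (written to `scratch/cohort/`, outputs to `results/`):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_normalize_and_qc.py
python analysis/03_differential_reactivity.py
python analysis/04_cluster_heatmap.py
python analysis/05_elisa_paired_t.py
```

`02_normalize_and_qc.py` prints:

```
normalized 20 arrays (768 collapsed antigen values each)
  background estimates: 45.6-48.6 raw units; floored antigen spots: 0
  duplicate-spot correlation: mean r = 0.980 (range 0.978-0.981, n = 20)
  PL/SF correlation:          mean r = 0.960 (range 0.957-0.962, n = 10)
```

i.e. duplicate spots on the same slide agree at `r ≈ 0.98` and each
patient's plasma profile tracks their synovial fluid at `r ≈ 0.96` —
the reproducibility regime in which fold-change screening is meaningful.
`03_differential_reactivity.py` then recovers every planted category:

```
differential calls over 768 antigens: {'similar': 738, 'pl_higher': 29, 'sf_higher': 1}
planted-category recovery (called-as-planted / planted): {'pl_higher': '29/29', 'sf_higher': '1/1', 'similar': '6/6'}
```

(background antigens legitimately fall in the <10% "similar" band), and
`04_cluster_heatmap.py` reports that the k=2 UPGMA cut of the plasma
sample tree separates the planted low/high antibody-level patient groups
with adjusted Rand index 1.00.

The same steps are available as a console tool
(`seroarray simulate|normalize|qc|diff|cluster|elisa|run`); the published
36-antibody differential list and the 10-patient demographics table ship
as packaged fixtures (`seroarray.load_table1_fixture()`,
`load_table2_fixture()`).

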