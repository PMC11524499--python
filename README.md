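# ramclav

Raman microspectroscopy chemometrics of cortical bone: preprocessing,
true-peak-height band metrics, phosphate-FWHM crystal maturity, and
PCA-LDA cohort analysis, with a calibrated synthetic clavicle-cohort
generator for end-to-end testing.

## The problem

Raman spectra of cortical bone carry a compact chemical summary of the
tissue: the phosphate ν1 band (~960 cm⁻¹) reports hydroxyapatite mineral,
carbonate (~1070 cm⁻¹) reports lattice substitution, and the amide III
(~1270 cm⁻¹), CH₂ (~1450 cm⁻¹), amide I (~1670 cm⁻¹) and proline
(~850 cm⁻¹) bands report the collagenous matrix.  Bioarchaeological and
clinical studies compare these signals across individuals — by age,
skeletal side, and sampling location along a bone — to ask how chemistry
changes with aging and mechanical loading.  This package implements that
analysis chain for cohorts of clavicle measurements:

1. **Preprocessing** — crop to 594–1704 cm⁻¹, iterative order-7
   polynomial baseline correction (clip-above-fit fluorescence removal),
   vector normalization to unit Euclidean norm.
2. **Band metrics** — *true peak heights* (apex intensity minus the
   baseline reference at the apex, apex refined by parabolic
   interpolation), the mineral-to-matrix ratio H₉₆₀/H₁₄₅₀, the
   intra-mineral ratio P:C = H₉₆₀/H₁₀₇₀, the mineral-to-protein ratio
   P:A = H₉₆₀/H₁₂₇₀, and crystal maturity as the full width at half
   height (FWHM) of the phosphate peak (narrower ⇒ more mature mineral).
3. **Chemometrics** — PCA (mean-centred, 10 components by default)
   followed by LDA solving S_b v = λ (S_w + εI) v on the retained scores;
   C classes give C−1 discriminants (LD1, LD2).  Discriminants are mapped
   back to wavenumber space and each band window is scored by its maximum
   absolute loading to attribute the separation to chemistry.
4. **Cohort designs** — five standard groupings (by age; by age within
   side; medial vs lateral; left vs right per region; along-bone
   position), each run as its own PCA-LDA with ratio summaries, maturity
   rankings and guarded monotone-trend flags.

Because the physical specimens such studies rest on are museum objects
with no public spectra, the package ships a synthetic cohort generator
(`synthetic_cohort`): 22 clavicles × 15 anterior-surface measurements
with pseudo-Voigt bone bands, smooth fluorescence background, log-normal
between-individual and per-measurement variability, and group-level
effects (mineral rising with age, protein falling, right side and medial
region mineral-elevated).  The generator is calibrated so the pipeline's
cohort-mean 960:1450 ratio equals 8.01, the benchmark value for
well-preserved collagen.

## Worked example

```python
import ramclav as rc

spec = rc.default_cohort_spec(seed=1)      # calibrated study conditions
cohort = rc.simulate_cohort(spec)          # 330 spectra, 22 clavicles
processed = rc.preprocess_set(cohort)      # crop -> baseline -> normalize
table = rc.cohort_metrics(processed)       # heights, ratios, FWHM

print("mineral:matrix (960:1450):", round(table["ratio_960_1450"].mean(), 3))
print(table.groupby("age_group")[["ratio_p_a", "fwhm_960"]].mean().round(3))

res = rc.pca_lda(processed, "age_group")   # scores, loadings, attribution
print(res.attribution.table.head(3).to_string(index=False))
```

prints

```
mineral:matrix (960:1450): 8.01
           ratio_p_a  fwhm_960
age_group
13-18          6.700    17.019
18-30          7.158    17.264
30-40          8.071    16.578
 ld      band    score  rank
LD1 phosphate 0.222176     1
LD1 carbonate 0.018234     2
LD1   amide_i 0.017993     3
```

The cohort-mean mineral-to-matrix ratio of 8.01 indicates well-preserved
collagen.  The mineral-to-protein ratio P:A rises monotonically from the
youngest (6.70) to the oldest group (8.07) — increasing mineralization
with age — while the phosphate FWHM is smallest in the oldest group
(16.58 cm⁻¹): its mineral is the most mature.  The LD1 band attribution
puts phosphate first by an order of magnitude: the age separation is
driven by mineral chemistry.

The same stages are available from the shell:

```sh
ramclav simulate  --seed 1 --out-dir raw/
ramclav preprocess --in-dir raw/ --out-dir prep/
ramclav metrics   --in-dir prep/ --out metrics.csv --group-by age_group,side
ramclav pcalda    --in-dir prep/ --label age_group --out-prefix out/age
ramclav run       --simulate --seed 1 --out-dir results/
```

`ramclav run` executes all five designs and writes per-analysis scores,
loadings, attribution, ratio and maturity tables (CSV), plots (PNG), and
a JSON run manifest; identical input and config give byte-identical
tables.

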