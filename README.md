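# dabquant

Quantitative analysis of DAB immunohistochemistry (IHC) photomicrographs
by positive pixel counting: classify every pixel of a hematoxylin-
counterstained, DAB-developed image as negative or weak / medium /
strong positive, restrict the tally to annotated regions of interest
(tumor or epidermis in, stroma or dermis out), summarize each tissue
core as an H-score, and compare cohorts defined by TNM staging with a
two-tailed unpaired t-test.

It is aimed at researchers who score biomarker expression (for example
a tumor suppressor such as PTEN) on tissue-microarray cores and want
the whole pipeline — classification, ROI masking, scoring, statistics —
as a reproducible, scriptable library instead of an interactive slide
viewer. Because original slide sets are rarely shareable, the package
includes a stain-physics synthetic generator that renders DAB +
hematoxylin images with per-pixel ground truth, so every stage of the
pipeline is testable end to end without any external data.

## The method

A pixel with RGB value (R, G, B) is converted to hue h, saturation s,
and intensity I = (R + G + B)/3. Bright, unsaturated pixels
(I ≥ 230, s < 0.04 by default) are bare glass and are excluded. A pixel
is a positive candidate when its hue lies within a window centered on
the DAB brown (default center 0.1, width 0.5 on the unit color wheel)
and s ≥ 0.04; candidates are binned by intensity,

- strong: I ≤ 100,
- medium: 100 < I ≤ 175,
- weak: 175 < I ≤ 220,

and everything else is negative. With f_w, f_m, f_s the weak / medium /
strong fractions of the analyzed (non-excluded, in-ROI) area, each core
receives the histochemical score

    H = 1·f_w + 2·f_m + 3·f_s,   0 ≤ H ≤ 3.

Cohorts (headline grouping: Breslow-thin T1+T2 versus thick T3+T4
melanoma) are summarized by mean H and SEM, their ratio is reported as
a fold change, and group means are compared with a two-tailed unpaired
t-test (pooled-variance Student by default, Welch by flag),
significant at p ≤ 0.05.

The synthetic generator renders pixels by Beer–Lambert mixing,
`I_c = 255·10^(−(h·H_c + d·D_c))` per channel, using the standard
hematoxylin (0.65, 0.70, 0.29) and DAB (0.27, 0.57, 0.78)
optical-density vectors, with DAB concentrations calibrated by
bisection to the midpoint of each intensity bin.

## Worked example

`examples/04_cohort_comparison.py` simulates the study design — 8 thin
and 75 thick melanoma cores with generator targets putting the group
mean H-scores at 0.95 and 0.57 — scores every rendered core through the
full image pipeline, and compares the groups:

```
thin:  n= 8  mean H = 0.966  SEM = 0.093
thick: n=75  mean H = 0.554  SEM = 0.018
fold change = 1.743 (decrease in thick)
t = 6.527, df = 81, p = 5.43e-09 -> significant at alpha = 0.05
```

The thin-group mean recovers its 0.95 target within sampling noise of
an 8-core arm, the thick group sits near 0.57, and the fold change
(reference group = thin, so a ratio above 1 reads as an "x-fold
decrease" in thick tumors) lands near 1.7 with a clearly significant
t-test. The other examples render a single core and print its exact
ground-truth H-score (`01`), tabulate per-class pixel counts and write
the red/orange/yellow/blue overlay (`02`), and score a core under an
include + exclude ROI annotation (`03`).

The same pipeline is available from a shell:

```sh
dabquant simulate --config config.yaml --out cohort/ --seed 1
dabquant score    --images cohort/metadata.csv --out scores.csv
dabquant cohort   --scores scores.csv --group-by thickness --out report/
```

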