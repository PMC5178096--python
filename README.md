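# lastrain

Left-atrial (LA) function from cine CMR contours, and cardiac fat from
2-point Dixon volumes — a tested analysis pipeline for studying early
diastolic dysfunction, exercised end to end on synthetic phantoms with
known ground truth.

## The problem

The earliest imaging signs of diastolic dysfunction — the kind that
precedes HFpEF in obesity and type 2 diabetes — show up in left atrial
mechanics before chamber sizes or ejection fractions move. Feature-tracked
LA strain quantifies those mechanics from ordinary cine acquisitions, and
Dixon imaging quantifies the epicardial fat burden suspected of driving
them. This package implements the full measurement chain for both, plus
the two-group cohort statistics used to compare patients against controls.

## What it computes

From per-frame endocardial contours of the three long-axis views
(2-chamber, 4-chamber, 3-chamber):

- **Longitudinal strain** Sl(t) = (Lt − L0)/L0, the fractional change of
  contour length relative to the trigger frame;
- **Radial motion fraction** Mr(t) = (Mt − M0)/M0, the fractional change of
  per-segment radii toward the reference-frame centre of mass;
- **Strain rates** SRl, Vr as temporal derivatives (s⁻¹);
- **Phasic indices** for the reservoir (R), conduit (C) and atrial
  contraction (A) phases — Sl_R/C/A, Mr_R/C/A, the rate peaks S′/E′/A′ and
  the E′/A′ and A/R ratios — with R = C + A exact by construction, averaged
  across views for a global readout;
- **MV decomposition**: each segment's displacement resolved along the axis
  toward the mitral-valve centre (cMr, intrinsic atrial motion) and
  perpendicular to it (pMr, broadly the ventricular drag).

From Dixon fat/water volumes: the septal-ROI intra-myocardial fat fraction
(mean F/(F+W)), and the epicardial fat volume/fraction by seeded K-means
clustering of fat intensities inside a whole-heart mask, indexed to BSA.

Cohort layer: Shapiro–Wilk-gated group comparisons (t test vs
Mann–Whitney U), Pearson correlations, intra-observer ICC(2,1), and
percent-change summaries.

## Worked example

```bash
python analysis/01_simulate_phantoms.py
python analysis/02_strain_analysis.py
```

prints

```
3 views analyzed -> results/strain
     index  measured   truth
      sl_r     33.05   33.20
      sl_c     16.30   16.50
      sl_a     16.76   16.70
Mr_R 36.53% (exceeds Sl_R: the phantom's ventricular-drag translation
registers as radial motion, as intended)
decomposition: cMr_A 20.3%  pMr_R 53.3% (control-cohort scale)
```

The phantom's reservoir strain target of 33.2% (a healthy-control value) is
recovered to 0.4% relative at 20 cine phases; the contraction amplitude
(16.7%) and the derived conduit amplitude (16.5%) follow with the exact
additivity Sl_R = Sl_C + Sl_A. The decomposition readouts sit at the
healthy-control scale because the phantom's translation amplitudes model a
ventricle dragging the atrium ~13 mm along and ~16 mm across the MV axis.

Continue with `03_fat_quantification.py` (Dixon phantom: a 177.9 mL
epicardial fat shell recovered exactly at SNR 10, septal fat fraction 6%),
`04_cohort_analysis.py` (a full 19-control / 20-patient simulated cohort
through every stage, with the conduit-phase and E′/A′-ratio group
differences coming out significant, as expected from the effect sizes), and
`05_published_arithmetic.py` (percent changes between published group
means).

The same functionality is available as a CLI (`lastrain simulate|strain|
fat|cohort|run-all`) and as a library (`lastrain.strain`,
`lastrain.decomposition`, `lastrain.fat`, `lastrain.stats`, ...).

## Layout

- `src/lastrain/` — the library: geometry primitives, strain engine, MV
  decomposition, volumetrics, Dixon fat quantification, cohort statistics,
  phantom generators, IO, pipeline, CLI
- `analysis/` — numbered narrative drivers writing to `results/`
- `tests/` — pytest suite (unit, property and end-to-end)
- `docs/methods.md` — models, conventions, parameter choices, limitations
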