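# breathgate

End-tidal breath gas segmentation and electronic-nose health-status
classification, as a tested Python library.

Exhaled human breath carries endogenous volatile biomarkers (hydrogen,
methane, hydrogen sulfide, carbon monoxide, propane, acetone, ethanol), but
only the **end-tidal** portion of an exhalation — the final ~70% by volume,
coming from the alveoli — reflects blood metabolism. The first ~30% is
**anatomical dead-space gas** from the conducting airways, compositionally
close to ambient air, and it dilutes every biomarker it touches. An
electronic nose that stores the whole breath therefore analyzes a
contaminated mixture; one that gates its collection valve on expiratory
flow can store nearly pure alveolar gas.

`breathgate` implements the full computation chain of such a flow-gated
device for researchers in breath analysis / volatilomics who want to study
the segmentation rule, its sensitivity, and its downstream effect on
classification — without the hardware:

* **Flow segmentation.** From a pre-experiment expiratory flow trace
  Q(t), the cumulative volume V(t) = ∫₀ᵗ Q dt gives the dead-space volume
  V₂ = 0.3 (V₁+V₂), the time t₁ with V(t₁) = V₂ (dead space past the flow
  meter), and the time t₂ with V(t₂) = V(t₁) + V₃ (dead-space front past
  the gas container of volume V₃). The expiratory flow at t₂ is the
  subject's **separation threshold**; three pre-experiment breaths are
  averaged.
* **Acquisition state machine.** CLEANING → DEAD_SPACE_REMOVAL →
  COLLECTION → DETECTION, with an armed below-threshold trigger, and an
  exact accounting of the dead-space fraction of the stored gas.
* **Synthetic study generator.** Health labels from a six-item self-assessed
  scale (total ≤ 45 poor, 46–55 good, ≥ 56 excellent), class-dependent
  log-normal breath VOC concentrations, dead-space dilution
  c = (1−f)·c_alv + f·c_amb, and a 10-channel MOS sensor array
  (conductivity ratio R_g = G_gas/G_air, power-law steady state, two-time-
  constant rise, first-order recovery, multiplicative noise).
* **Features.** Mean filtering plus five per-channel descriptors
  (integration ratio, maximum location, maximum first derivative, two
  spectral magnitudes) → a 50-dimensional feature vector.
* **Classification.** Fisher LDA from the scatter matrices S_w, S_b
  (generalized eigenproblem S_b ω = λ S_w ω, two leading eigenvectors),
  one-vs-one soft-margin RBF-SVM (3 pairwise machines, majority vote),
  genetic-algorithm search over (c, γ), KNN, random forest, a PCA-to-3D
  baseline, and stratified five-fold cross-validation with per-class
  recall / precision / F1.

## Worked example

Segmenting one synthetic 500 mL exhalation
(`python examples/01_segment_breath.py`):

```
total exhaled volume :   500.0 mL
dead-space volume    :   150.0 mL (30% of total)
end-tidal volume     :   350.0 mL
t1 (dead space clear):   0.565 s
t2 (container clear) :   0.888 s
flow threshold       :   15.70 L/min
```

The 500 mL breath carries the textbook 150 mL of dead space; once 150 mL
(plus the 100 mL container volume) has passed the flow meter, the flow has
decayed to 15.7 L/min — the value at which this subject's collection valve
should switch.

Running the classification stack on the default synthetic cohort
(`python examples/04_classify.py`):

```
GA-selected hyperparameters: c = 17, gamma = 7.95 (fitness climbed 0.965 -> 0.974)

clean end-tidal collection (dead fraction 0):
class          recall  precision       F1     n
excellent      94.7%     97.3%   96.0%    38
good           97.4%     94.9%   96.1%    38
poor          100.0%    100.0%  100.0%    39
overall accuracy: 97.4%

whole-breath collection (dead fraction 0.3):
...
overall accuracy: 88.7%

accuracy cost of dead-space contamination: 8.7 percentage points
```

With clean end-tidal gas the LDA + GA-tuned SVM pipeline classifies the
three health classes at 97% five-fold CV accuracy; storing the whole breath
(30% dead-space contamination, varying breath to breath) costs about nine
points — the quantitative case for flow-gated collection.

The other examples cover collection contamination and threshold sensitivity
(`02`) and cohort generation with per-sensor feature summaries (`03`). A
thin CLI mirrors the library (`breathgate simulate-breath`, `threshold`,
`collect`, `simulate-cohort`, `features`, `train`, `run`, `report`).

## Layout

```
src/breathgate/     flow.py        flow traces + breath generator
                    separation.py  threshold separation rule
                    acquisition.py valve state machine + contamination
                    cohort.py      synthetic cohort + MOS sensor model
                    features.py    filtering + 50-dim feature extraction
                    learn.py       LDA / SVM+GA / KNN / RF / PCA / CV
                    io.py          CSV & JSON formats, end-to-end runner
                    cli.py         thin command-line interface
examples/           one narrative script per capability
docs/methods.md     model assumptions, parameters, limitations
```
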