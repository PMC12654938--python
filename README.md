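# screeneval

Combined subjective–objective weighted evaluation and ranking of stroke-screening
base hospitals.

## The problem

The China National Stroke Screening Surveys (CNSSS) grade each participating
base hospital on eleven banded performance indicators (task completion,
risk-factor control, detection and intervention rates, follow-up completion,
age-structure deviation). The programme's original report card simply sums the
awarded points — implicitly weighting every indicator equally — which lets
near-ceiling compliance indicators mask real performance differences.
`screeneval` implements a combined-weight evaluation model for such panels,
aimed at programme evaluators and health-services researchers:

* **subjective weights** from the expert-assigned indicator scores,
  `W_j = S_j / Σ_k S_k`;
* **objective weights** by the entropy weight method (EWM): min–max
  normalisation per indicator attribute (positive / moderate / negative), a
  +0.001 shift, column proportions `P_ij`, information entropy
  `E_j = −(1/ln n) Σ_i P_ij ln P_ij`, and weights `W_j = (1−E_j) / Σ_k (1−E_k)`
  — indicators that vary more across hospitals weigh more;
* **combined weights** by multiplicative synthesis with normalisation (MSN):
  `W_j = Π_l W_jl / Σ_k Π_l W_kl`;
* **total weighted scores** `TWS_i = Σ_j W_j X_ij` and competition rankings
  per methodology;
* **agreement metrics** between methodologies: the head–tail consistency rate
  `S = (x + y) / (0.4 n)` over the top/bottom `floor(0.2 n)` sets, and the
  discrimination degree `D` built from squared gaps of affinely standardised
  scores `V_i = n (1 − |V'_i − V'_1| / (V'_1 − V'_n))`.

A seeded synthetic generator produces panels of banded point scores with
controllable per-indicator dispersion and ceiling effects, so the whole
pipeline is testable without programme data.

## Worked example

The published sixteen-hospital Sichuan panel ships as a transcription
(`screeneval.reference_tables()`). Combining its printed subjective and
objective weight vectors and comparing its rankings:

```python
>>> import screeneval as se
>>> ref = se.reference_tables()
>>> combined = se.combine_msn([ref.subjective, ref.objective])
>>> round(combined["X9"], 4)   # Intervention Rate dominates the combination
0.2303
>>> round(combined["X1"], 4)   # Task Completion Rate collapses from 0.3125
0.0995
>>> float(se.weight_change(ref.subjective, ref.objective).loc["X1", "pct_change"])
-92.448
>>> se.head_tail_consistency(ref.rankings["combined"], ref.rankings["objective"])
0.9375
>>> se.head_tail_consistency(ref.rankings["subjective"], ref.rankings["original"])
0.625
```

The combined weight 0.2303 says the Intervention Rate carries almost a quarter
of the composite score once expert priority and data variability are both
honoured, while the Task Completion Rate — subjectively dominant at 0.3125 —
loses 92.4 % of its weight under the entropy route because nearly every
hospital sits at its ceiling. The head–tail rate 0.9375 is the attainable
maximum at n = 16 (top-3 and bottom-3 sets coincide exactly between the
combined and objective rankings); 0.625 means the subjective and original
methodologies agree on only four of those six extreme slots.

From the shell, on your own data:

```sh
screeneval score    --rates rates.csv --standards standards.yaml -o points.csv
screeneval evaluate --matrix points.csv -o report/
screeneval compare  --report report/
screeneval simulate --n 16 --seed 42 -o synth.csv
```

`evaluate` writes `weights.csv`, `rankings.csv`, `weight_changes.csv`,
`comparisons.csv` and a machine-readable `report.json`.

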