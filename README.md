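# blebkin

Quantitative analysis of nuclear blebbing as a chromatin-loss route in the
aging *C. elegans* hypodermis.

Aged worms accumulate protrusions ("blebs") of the nuclear envelope on their
hyp7 hypodermal nuclei — from close to zero per nucleus on adult day 1 (AD1)
to about 35 blebs per 100 nuclei by AD14. Occasionally a bleb detaches and
carries chromatin into the cytoplasm, where lysosomes degrade it. The question
this package answers at desk scale: **how much of the age-related somatic DNA
loss can bleb detachment account for?** The answer — about 0.1% — comes from
three linked calculations, each implemented and tested here:

1. **Detachment kinetics** (`blebkin.kinetics`). Time-lapse bleb tracks are
   censored survival data. Under a constant hazard λ the maximum-likelihood
   estimate is the occurrence/exposure ratio

   λ̂ = D / Σᵢ tᵢ,

   with D the number of detachments and tᵢ each bleb's at-risk time; the mean
   bleb lifetime is 1/λ̂ and the half-life ln2/λ̂. Tracking 97 blebs for 8 h
   with a single detachment (4 h at risk) gives 772 bleb-hours of exposure,
   hence a lifetime of 772 h and a half-life of ≈535 h. Because event counts
   are tiny, confidence intervals use the exact Poisson (Garwood) construction
   from gamma quantiles.

2. **Age trajectory** (`blebkin.trajectory`). The expected standing bleb count
   per nucleus, B(t), is represented either as a piecewise-linear
   interpolation of counted frequencies or as a power law
   B(t) = B_max·((t−t₀)/(T−t₀))^p. Since each standing bleb detaches with
   hazard λ, the expected detachments per nucleus over an age window is
   λ_day·∫B(t)dt. With the default reconstruction (p = 2, 0 → 0.35
   blebs/nucleus over AD1–AD14) this integral is 1.517 bleb-days and the
   expected detachments per nucleus ≈ 0.047.

3. **Chromatin-loss budget** (`blebkin.budget`). Multiplying expected
   detachments by the chromatin-positive bleb fraction (42%) and the per-bleb
   DNA fraction — a bleb has ~1/5 the nuclear diameter, hence (1/5)³ = 1/125 =
   0.8% of its volume and, by assumption, of its DNA — gives the fraction of
   hyp7 nuclear DNA lost through blebbing (≈0.016%). Dividing by the total
   somatic DNA loss over the same period (10–25%, midpoint 15%) puts
   blebbing's share at ≈0.1%.

A stochastic simulator (`blebkin.synthetic`) generates all study inputs: bleb
births follow a nonhomogeneous Poisson process whose intensity is calibrated
so the analytic standing mean reproduces any target trajectory, detachment
delays are exponential, chromatin content is Bernoulli(0.42), and samplers
emit cross-sectional frequency tables and frame-quantised censored track
tables with full seed determinism.

## Worked example

Build the reconstructed 97-track table and run the full pipeline:

```python
from blebkin import BlebTrack, write_tracks

tracks = [BlebTrack(f"t{i:03d}", 0.0, 8.0, False) for i in range(96)]
tracks.append(BlebTrack("t096", 0.0, 8.0, True, event_time=4.0))
write_tracks(tracks, "tracks.tsv")
```

```sh
echo '{"tracks": "tracks.tsv"}' > config.json
blebkin run --config config.json
```

The report (abridged) prints:

```json
{
  "kinetics": {
    "n_tracks": 97,
    "n_events": 1,
    "exposure_bleb_hours": 772.0,
    "rate_per_hour": 0.0012953367875647669,
    "mean_lifetime_hours": 772.0,
    "half_life_hours": 535.1096233922777,
    "rate_ci_per_hour": [3.279508806255168e-05, 0.0072171546514752565]
  },
  "expected_detachments_per_nucleus": 0.04715025906735751,
  "budget": {
    "hyp7_loss_fraction": 0.00015842487046632126,
    "hyp7_loss_percent": "0.016%",
    "share_of_total": 0.0010561658031088084,
    "share_of_total_percent": "0.1%",
    "share_range": [0.000633699481865285, 0.0015842487046632125]
  }
}
```

Reading it: one detachment in 772 bleb-hours gives the 772-h mean lifetime
(95% CI on the rate spans 3.3×10⁻⁵–7.2×10⁻³ per hour — a single event
constrains it weakly); integrating the default trajectory against that rate
predicts 0.047 detached blebs per nucleus by AD14; and the budget puts the
blebbing route at 0.016% of hyp7 nuclear DNA, i.e. ~0.1% of the 15% total
somatic loss (0.06–0.16% across the 10–25% denominator range). Blebbing is a
real but minor chromatin-loss route.

Other subcommands: `blebkin simulate` (synthetic study bundles),
`blebkin estimate-kinetics`, `blebkin trajectory`, `blebkin budget`.

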