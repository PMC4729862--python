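# tarpgate

Kinetic modelling of AMPA-type glutamate receptors in complex with TARP
auxiliary subunits (Stargazin/γ-2, γ-8), for ion-channel biophysicists who
want to simulate fast-perfusion patch-clamp protocols against an explicit
Markov mechanism and reproduce the model-level signatures of **TARP
superactivation**: the slow activity-dependent growth of the steady-state
current, the transient overshoot in two-pulse recovery curves
("suprarecovery"), and the correlation between recovery rate and the
TARP-induced steady-state gain across a series of ligand-binding-domain
mutants.

## The model

The receptor is a single-binding-site Markov chain. The TARP-less layer is

```
            k+·c / k-         β / α
       R  <---------->  AR  <------->  AR*        (open, g = 0.4)
       |                 |  \
       |  k+·c / kd-     |   \  d0+ / d0-
       +------------> AD1     AD0                 (desensitized)
                        |
                        |  d2+ / d2-
                       AD2                        (deep desensitized)
```

The TARP complex duplicates every state into a second layer in which the
TARP is in its *active* conformation: channel opening is boosted
(β_s = 5×10⁵ s⁻¹ replaces β = 8×10³ s⁻¹), the deep desensitized exit uses
d2\*, and the open state conducts 2.5-fold more (g = 1.0 vs 0.4). The two
layers are joined by TARP activation steps — s+/s− = 0.07/1 s⁻¹ on every
closed pair, s\*+/s\*− on the open pair. Enforcing microscopic
reversibility (the Kolmogorov cycle criterion, residual ≤ 10⁻¹⁰) then
*forces* s\*+ ≫ s+: channel opening promotes the TARP into its active
state. That single thermodynamic fact generates the whole phenomenology —
a small basally superactive pool (~6.5% of complexes at rest), positive
feedback during activity, superactivation, suprarecovery, and
depression-then-repotentiation during trains.

The mutant series (trials 0–8) varies the deep desensitized exit rates
(d2−, d2\*−) over two and a half orders of magnitude, with a compensating
adjustment of the basal shutting rate α anchored to the deactivation
rates of reference receptors; the superactive complex's shutting is a
TARP property pinned to the wild-type value, so reversibility converts
the α compensation into a trial-dependent TARP activation rate s\*+ —
weakly gating mutants promote their TARPs harder when open. Trial 7 is
the wild-type proxy.

Variants: `noTARP`, `TARP`, `TARP+CTZ` (desensitization blocked),
`kainate` (weak partial agonist), and two deliberately broken geometries
used as controls, `alt-binding` (slow glutamate unbinding instead of a
gating boost) and `alt-equal-conductance`.

## Worked example

```python
import tarpgate as tg

tarp = tg.balanced_scheme("TARP", trial=7)     # build + balance
print(round(100 * tg.basal_superactive_fraction(tarp), 2))  # -> 6.54

trace = tg.simulate(tarp, tg.make_pulse(5.0, 0.01))  # 5 s of 10 mM glutamate
res = tg.superactivation(trace)
print(round(res.magnitude, 1), round(res.rate, 2))   # -> 15.8  2.37
```

6.54% of complexes are already superactive at rest; during a long
glutamate application the current sags into a trough and then climbs back
by 15.8% of the peak at 2.4 s⁻¹ — superactivation.

The same from the command line:

```
$ tarpgate fit
         trial    k_des  k_deact  k_deact_slow  deact_slow_frac  iss_pct  peak_popen   k_rec recovery_model
variant
noTARP       7  130.641  949.399       949.348            0.499   11.055       0.644  14.979             HH
TARP         7   52.972  775.555        92.579            0.256   66.302       0.666   6.642  biexponential
```

The TARP complex shows the larger peak open probability and steady-state
current, apparently slower desensitization (weighted 53 vs 131 s⁻¹), and a
pronounced slow deactivation component (93 s⁻¹, 26% of amplitude) — the
superactive sub-population closing down.

```
$ tarpgate experiment correlation
       k_rec_noTARP  iss_noTARP  iss_TARP  fold_iss
trial
0            0.1246      0.3500    1.1366    3.2470
...
7           14.9786     11.0501   72.4758    6.5588
8           29.0250      9.0621  134.4013   14.8311
expectations: {'positive_slope': True, 'monotone': True}
```

The fold-increase in steady-state current rises monotonically with the
recovery rate across the mutant series — the mechanism's headline
prediction.

Other entry points: `tarpgate check` (balancing report),
`tarpgate experiment overshoot|superactivation|trains|reject-binding|
reject-conductance`, `tarpgate simulate -c config.yaml`, and
`tarpgate synth` for noisy synthetic "recordings" with ground truth
(20 kHz sampling, 10 kHz low-pass, 300 µs solution exchange, additive
noise).

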