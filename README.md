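# killitox

From larval-fish behavior assays and brain expression counts to
population-relevant predictions.

Embryonic exposure to neurotoxicants such as methylmercury (MeHg) and
PCB126 produces sublethal changes in larval fish — altered swimming,
feeding and brain gene expression — that are invisible to classical
lethality endpoints but can matter enormously at the cohort level.  This
package implements, as a tested pipeline, the computational chain used to
quantify that link in Atlantic killifish (*Fundulus heteroclitus*) from a
reference site (Scorton Creek, SCO) and a PCB-adapted site (New Bedford
Harbor, NBH):

1. **Behavior endpoints** (`trajectory_endpoints`) — distance traveled,
   swimming bouts, step lengths, circular turning-angle statistics, startle
   magnitude at light transitions, and the five feeding-assay endpoints,
   per larva and per assay period.
2. **Movement HMM** (`movement_hmm`) — a 3-state (slow/medium/fast) hidden
   Markov model over step-length/turning-angle series with gamma and
   von Mises emissions, fitted by Baum–Welch EM pooled across larvae.  The
   staying probabilities P(i→i), transition probabilities P(i→j) and
   per-state emission summaries are themselves behavior endpoints.
3. **Trend calling** (`treatment_stats`) — each endpoint is summarized as
   Pos/Neg/NS over the five ordered treatment comparisons
   (SCO-Ctrl vs SCO-MeHg, SCO-Ctrl vs SCO-PCB, SCO-Ctrl vs NBH-Ctrl,
   SCO-PCB vs NBH-PCB, NBH-Ctrl vs NBH-PCB).  Behaviors use a Bayesian
   normal mean-difference model (call by 95% credible interval); genes use
   per-gene negative-binomial GLMs with library-size offsets and
   Benjamini–Hochberg FDR control at 0.05; gene sets use direction-aware
   hypergeometric over-representation.  At a per-test alpha of 0.05 across
   the 83-endpoint battery, 0.05 × 83 = 4.15 endpoints are expected
   significant by chance.
4. **Pattern concordance** (`pattern_concordance`) — genes and behaviors
   whose ±/0 trend vectors are identical (or exactly sign-flipped) across
   the comparison plan are grouped and matched, linking e.g. a gene
   down-regulated under both chemicals with a feeding behavior decreased
   under both.
5. **Individual-based model** (`ibm`) — 2500 larvae per replicate, 10
   replicates, tracked daily from hatch to juvenile length or 100 days.
   Treatment effects enter only through behavior multipliers
   (treatment/control ratios of swim speed, capture success, handling time,
   reactive distance) acting on a 2-D search-area foraging model with a
   bioenergetic growth rule and size-dependent mortality.  Outputs are
   per-replicate percent survival and survivor growth (mm/d).

A `synthetic_data` module generates every input the pipeline consumes —
multi-state correlated random walks, light/dark visual-motor-response (VMR)
trajectories, Poisson/Bernoulli feeding events and negative-binomial count
matrices with planted fold-changes — so the whole chain is testable without
any external download.

## Worked example

Simulate a 20,000-step trajectory from a known 3-state movement model,
refit it, and read off the HMM behavior endpoints:

```python
import killitox as kx
from killitox import movement_hmm as mh

params = kx.MovementHMMParams(
    transition_matrix=[[0.90, 0.08, 0.02], [0.10, 0.80, 0.10], [0.05, 0.15, 0.80]],
    step_params=[[0.2, 0.1], [1.0, 0.4], [3.0, 1.0]],   # (mean, sd) mm per state
    angle_params=[[0.0, 0.5], [0.0, 2.0], [0.0, 8.0]],  # (mean, concentration)
)
traj, states = kx.gen_trajectory(params, 20_000, seed=1)
fit = mh.fit_movement_hmm(mh.series_from_trajectory(traj), n_states=3,
                          n_restarts=3, seed=0)
print(fit.transition_matrix.round(3))
print(mh.hmm_behavior_endpoints(fit).head(4))
```

prints

```
[[0.9   0.083 0.016]
 [0.103 0.797 0.101]
 [0.051 0.143 0.806]]
                        endpoint     value
0             hmm_stay_prob_slow  0.900327
1  hmm_trans_prob_slow_to_medium  0.083331
2    hmm_trans_prob_slow_to_fast  0.016342
3           hmm_stay_prob_medium  0.796852
```

i.e. every transition probability of the generating chain is recovered to
within ±0.01, and the endpoints are emitted in the slow/medium/fast
vocabulary used downstream.  Feeding the PCB-style multiplier set into the
cohort model against its control:

```python
from killitox import ibm
cfg = ibm.IBMConfig()                       # 2500 larvae x 10 replicates
sc  = ibm.make_scenario("spring")
ctl = ibm.run_cohort(cfg, sc, ibm.DEFAULT_MULTIPLIERS["SCO-Ctrl"], seed=17)
pcb = ibm.run_cohort(cfg, sc, ibm.DEFAULT_MULTIPLIERS["SCO-PCB"], seed=17)
print(f"control: {ctl.mean_survival_pct:.2f}% survival, "
      f"{ctl.mean_growth_mm_per_day:.3f} mm/d")
print(f"SCO-PCB: {pcb.mean_survival_pct:.2f}% survival, "
      f"{pcb.mean_growth_mm_per_day:.3f} mm/d")
```

prints

```
control: 1.56% survival, 0.308 mm/d
SCO-PCB: 0.12% survival, 0.268 mm/d
```

— a control cohort in the low single-digit survival band typical of larval
fish, and near-complete loss of the cohort when the measured PCB126
behavior deficits (slower swimming, longer prey handling, lower capture
success) are applied.

A thin CLI mirrors the pipeline stages
(`killitox simulate|endpoints|hmm|compare|de|patterns|ibm`); run any
subcommand with `--help`.

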