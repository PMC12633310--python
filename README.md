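# fretpharm

Single-molecule FRET trace analysis and receptor pharmacology fits for
studies of ligand-induced GPCR dimerization.

Allosteric ligands can act as molecular glues that pull two receptor
protomers into a dimer with altered signaling. Quantifying that claim
takes several independent measurements: single-molecule FRET to read out
conformational-state populations and inter-protomer distances,
dose–response assays for the potency of ligand-induced dimerization,
biosensor kinetics and equilibrium isotherms for transducer binding,
radioligand assays for orthosteric-site allostery, and spatial statistics
for receptor nanoclustering. `fretpharm` implements this full analysis
chain as a tested, reusable library, together with synthetic-data
generators so every stage can be verified by parameter recovery without
any external downloads.

## What it computes

**smFRET pipeline** (`fretpharm.fret`, `fretpharm.movie`): dual-view spot
detection and aperture photometry with local background correction;
donor-leakage subtraction (7 %); photobleaching step detection by
penalized least-squares changepoint segmentation; per-molecule γ from the
intensity exchange at the acceptor bleach; five selection criteria
(SNR ≥ 5, single-step acceptor bleach before donor bleach, γ ∈ [0.5, 2.5],
anticorrelated channels, single-step donor bleach if present); efficiency

&nbsp;&nbsp;&nbsp;&nbsp;*E* = *I*ₐ / (*I*ₐ + γ·*I*_d)

per frame over the both-dyes-active window; 30-bin histograms over
[−0.25, 1.25] normalized per molecule and averaged with equal molecule
weight; and a two-Gaussian fit whose normalized component areas are the
state populations.

**Pharmacology** (`fretpharm.binding`): three-parameter logistic
dose–response (pEC50), single-exponential 1:1 biosensor kinetics
(k_on, k_off, K_D = k_off/k_on), Langmuir steady-state affinity,
radioligand saturation and competition with the Cheng–Prusoff conversion
K_i = IC50/(1 + L/K_d), and donor-normalized ensemble FRET ratios.
All estimators follow the scikit-learn fit/attribute convention.

**Cluster statistics** (`fretpharm.clusters`): single-linkage nanocluster
assignment under a physical cutoff, cluster-size ECDFs, Mann–Whitney
rank-sum comparisons, and Gaussian-mixture EM for mass-photometry event
lists (with optional integer-multiple-of-monomer mean constraints).

**Synthetic data** (`fretpharm.synthetic`): two-state Markov FRET emitters
with bleaching, leakage and γ heterogeneity; rendered dual-view movies
with Gaussian PSFs and camera noise; dose–response tables; 1:1
sensorgrams; clustered point patterns; mass-event mixtures — each with a
ground-truth manifest.

## Worked example

```python
import numpy as np
from fretpharm import (AcquisitionConfig, PhotophysicsTruth, TwoStateTruth,
                       simulate_trace_set, analyze_traces)

# 300 molecules of a TM4-TM6 activation sensor: active (low-FRET, E=0.4)
# occupancy 26.5%, default photophysics (7% leakage, lognormal gamma,
# single-step bleaching, SNR ~ 10)
truth = TwoStateTruth.from_occupancy(1 - 0.265, E_states=(0.4, 0.8))
ts = simulate_trace_set(truth, PhotophysicsTruth(), AcquisitionConfig(seed=1), 300)

res = analyze_traces(ts.donor, ts.acceptor, sensor="tm4tm6")
print(f"accepted {res.n_accepted}/300 traces")
print("peaks:", np.round(res.model.means_, 3))
print("active fraction:", round(res.fractions["active"], 3))
```

Output:

```
accepted 159/300 traces
peaks: [0.402 0.798]
active fraction: 0.277
```

159 of 300 simulated molecules pass all five selection criteria; the
two-Gaussian fit finds components at E ≈ 0.40 and 0.80 (the generative
state efficiencies), and the low-FRET (active) component's area fraction,
0.277, recovers the 0.265 ground-truth occupancy within the
molecule-sampling error.

A binding example:

```python
from fretpharm import BLIKinetics, CurveTruth, simulate_curve_data

kd = 3.11e-6  # dimer-Gs affinity, M
truth = CurveTruth("bli_1to1", {"k_on": 0.05/kd, "k_off": 0.05, "r_max": 100,
                                "t_assoc": 180.0, "t_dissoc": 300.0, "dt": 1.0},
                   [30e-9, 100e-9, 300e-9, 1e-6, 3e-6, 10e-6])
est = BLIKinetics(t_assoc=180.0).fit(simulate_curve_data(truth))
print(round(est.equilibrium_.kd_ * 1e6, 3), "uM")   # -> 3.11 uM
```

A thin CLI wraps the same functions:

```
fretpharm simulate traces --occupancy 0.735 --n 300 --seed 1 --out sim/
fretpharm fret analyze --traces sim/traces.tsv --sensor tm4tm6 --out out/
fretpharm fit logistic --data doses.csv --out fit.json
fretpharm clusters analyze --points points.csv --cutoff 30 --out out/
```

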