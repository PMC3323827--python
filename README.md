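# gcalign

Model-based peak alignment for comprehensive two-dimensional gas
chromatography time-of-flight mass spectrometry (GC×GC/TOF-MS) peak
tables.

## Who this is for

Metabolomics groups running GC×GC/TOF-MS who need to align the detected
peak lists of replicate (or differently configured) runs before any
downstream analysis. Each analyte carries two retention times — RT1 on the
first column, RT2 on the modulated second column — plus a mass spectrum
and a peak area. Retention times drift between runs (dramatically so when
acquisition configurations differ, e.g. distinct temperature gradients),
and single metabolites are often reported as several peak entries within
one run. `gcalign` consumes ChromaTOF-style delimited peak tables and
produces matched peaks across runs, landmark-based retention-time
correction, and evaluation reports.

## The method

1. **Merge.** Within a run, entries sharing a compound identification
   collapse to the maximum-area entry.
2. **Score.** Every reference–target peak pair gets a mixture
   dissimilarity `S = w·D/(1+D) + (1−w)·C`, where `D` is the Euclidean
   distance between within-run elution-rank vectors (warp-invariant) and
   `C` is the spectral angle in degrees; smaller is more similar. Target
   peaks with `S < h` (default h = 40) form a reference peak's candidate
   set.
3. **Match.** A four-layer empirical Bayes model — presence `ρ`, claiming
   probabilities driven by neighborhood competition scores `(b, b*)`
   through quadratic-logistic layers, correctness `τ`, and normal score
   densities `f_T`/`f_F` — is fitted by EM; each claimed pair receives a
   posterior matching confidence `P[W=1 | Z=1, S; θ̂]`. Pairs above a
   cutoff (default 0.9) are retained one-to-one.
4. **Landmarks & RT adjustment.** Peaks matched through *every* run form
   landmark chains; chain-mean RTs define a representative grid. Per run
   and per dimension, all peaks move through a monotone piecewise-linear
   map `r_L + Δ(r_H − r_L)`, `Δ = (t − t_L)/(t_H − t_L)` between bracketing
   landmarks, with linear extrapolation outside the span.
5. **Evaluate.** Against the name-based gold standard (peaks sharing a
   compound key), report PPV, sensitivity and F1, optionally sweeping
   w × cutoff grids.

A synthetic-data module generates multi-run datasets with known ground
truth (affine RT warps, spectral noise, peak splitting, dropout,
compound-key misassignment) so every stage is testable without external
data. See `docs/methods.md` for the full model and its assumptions.

## Worked example

```python
import numpy as np
from gcalign import (heterogeneous_config, simulate_dataset, merge_peaks,
                     pairwise_match, align_runs, gold_standard_pairs, f1_score)

# three runs under different simulated temperature gradients
cfg = heterogeneous_config(n_metabolites=100, n_runs=3,
                           label_error_rate=0.0, seed=11)
runs, truth, master = simulate_dataset(cfg)
merged = [merge_peaks(r)[0] for r in runs]

# key-blind pairwise matching, scored against the name gold standard
gs = gold_standard_pairs(merged[0], merged[1])
pairs = pairwise_match(merged[0].strip_keys(), merged[1].strip_keys())
rep = f1_score(pairs, gs)
print(f"pairs={rep.n_predicted} gold={rep.n_gs} concordant={rep.n_tp} "
      f"PPV={rep.ppv:.3f} sensitivity={rep.sensitivity:.3f} F1={rep.f1:.3f}")

# landmark alignment of all three runs
adjusted, chains = align_runs([m.strip_keys() for m in merged])
rt1 = np.array([[r.by_id(c.members[r.run_id]).rt1 for r in merged] for c in chains])
rt1b = np.array([[r.by_id(c.members[r.run_id]).rt1 for r in adjusted] for c in chains])
print(f"landmark chains={len(chains)}")
print("RT1 sd across runs:", round(rt1.std(axis=1).mean(), 3), "min ->",
      round(rt1b.std(axis=1).mean(), 5), "min")
```

Output:

```
pairs=93 gold=93 concordant=93 PPV=1.000 sensitivity=1.000 F1=1.000
landmark chains=90
RT1 sd across runs: 5.654 min -> 0.00029 min
```

All 93 predicted pairs agree with the gold standard (F1 = 1.0 on this
clean-label dataset), 90 of ~96 merged peaks chain through all three runs
as landmarks, and the cross-run RT1 spread of landmark peaks collapses
from 5.65 min (the systematic inter-gradient shift) to well below a
modulation period.

## Command line

The same pipeline is exposed as a CLI:

```sh
gcalign simulate --preset heterogeneous --n-runs 3 --seed 7 --out-dir sim/
gcalign merge    sim/run00.tsv merged.tsv
gcalign match    sim/run00.tsv sim/run01.tsv --w 0.1 --cutoff 0.9
gcalign align    sim/run00.tsv sim/run01.tsv sim/run02.tsv --out-dir aligned/
gcalign evaluate sim/run00.tsv sim/run01.tsv --sweep
```

Global flags `--w`, `--h-threshold`, `--cutoff`, `--score-scale`, `--seed`
may also come from a YAML file via `--config`; command-line values win.
Input column layouts are configurable (`Dialect`), since ChromaTOF export
headers vary.

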