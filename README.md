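# netsi

Community-structure consistency analysis for multi-subject node time-series.

The package implements a complete analysis chain for asking whether a
continuous per-subject covariate (e.g. visual contrast sensitivity) is
associated with the spatial consistency of functional-network communities:

1. **`synthetic_cohort`** — generates test cohorts with planted community
   structure whose spatial fidelity in a target subnetwork is linearly linked
   (with clamping) to a truncated-normal covariate; includes motion traces
   with spike frames and a Pelli-Robson letter-count → log-CS converter.
2. **`signal_cleaning`** — framewise displacement (Power's formulation, 50 mm
   head radius), DVARS in percent-signal-change units, volume scrubbing at
   FD > 0.5 mm / DV > 0.5, zero-phase Butterworth band-pass (0.009–0.08 Hz),
   and confound regression (confounds are filtered with the same filter).
   Real-mode input: 4-D NIfTI + mask → node × time matrix.
3. **`network_build`** — Pearson correlation matrices thresholded to a fixed
   edge count `floor(N·K/2)` with `K = N^(1/S)` (so `S = log N / log K`),
   giving every subject the same connection density.
4. **`community_detect`** — Newman modularity `Q`, best-of-`n_runs` seeded
   Louvain restarts (igraph backend by default, networkx available), and a
   discrete-time Markov-stability evaluation whose value at time 1 equals `Q`.
5. **`scaled_inclusivity`** — node-wise SI = `|C∩T|² / (|C|·|T|)` of each
   subject community `C` against template subnetworks `T`, with group-mean
   and covariate-tertile summary maps.
6. **`distance_stats`** — weighted-Jaccard (Ružička) brain distances,
   absolute/mismatch covariate distances, pairwise distance regression with
   subject fixed effects (parametric standard-normal p and subject-level
   permutation p), and Benjamini–Hochberg step-up FDR (`adapted_fdr`).
7. **`pipeline` / `cli`** — end-to-end orchestration with per-stage
   serialization, provenance JSON, and seeded byte-identical reproducibility.

## CLI

```sh
netsi run-all --config pipeline.json --seed 7 --out out/
```

runs cohort → cleaning → networks → communities → SI → distance regression →
FDR, writing `results.tsv` (one row per model term, with the FDR column on
the covariate-of-interest family), per-template group/tertile SI maps, and
`provenance.json`. Individual stages are available as `simulate`, `clean`,
`network`, `communities`, `si`, and `regress`, each reading the previous
stage's plain-text artifacts so any step can be re-run. `PipelineConfig`
(see `netsi.pipeline`) is plain JSON; `mode` may be `synthetic` or `real`
(the latter takes a file manifest).

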