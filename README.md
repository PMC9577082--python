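# microstatekit

Resting-state EEG **microstate** analysis for two-group clinical
comparisons, with a fully ground-truthed synthetic cohort generator.

Spontaneous EEG can be described as a sequence of quasi-stable scalp
topographies ("microstates", ~50–125 ms each, conventionally four classes
A–D) whose temporal statistics — mean **duration**, **occurrence** rate,
time **coverage** and **transition probabilities** — shift with clinical
state.  `microstatekit` implements the standard analysis chain used to
compare such statistics between groups (here modelled on a study of young
smokers vs non-smoking controls with an FTND nicotine-dependence score),
and, because such recordings are rarely shared, also implements the
inverse problem: a semi-Markov generator that synthesizes whole cohorts
with known templates, known temporal parameters, planted group effects
and a planted covariate coupling, so that every stage of the chain can be
validated against a recoverable truth.

The chain:

1. preprocessing — average reference, zero-phase 1–20 Hz Butterworth
   band-pass, downsampling to 250 Hz, 2 s epochs, 80 µV amplitude
   rejection, ≥100-epoch inclusion gate;
2. GFP peak selection — local maxima of the global field power
   (GFP_t = population SD across channels), ≥10 ms apart, outliers above
   mean + 2 SD removed, 1,000 peaks per subject;
3. group-level **modified K-means** — polarity-invariant clustering of
   the pooled peak topographies (K = 4, 50 restarts, ≤1,000 iterations):
   assign frame *t* to `argmax_k (x_tᵀa_k)²`, update `a_k` to the
   principal eigenvector of `Σ_{t∈k} x_t x_tᵀ`; quality is the global
   explained variance `GEV = Σ_t (GFP_t·|corr(x_t, a_{L_t})|)² / Σ_t GFP_t²`;
4. canonical A–D ordering, backfitting by absolute spatial correlation,
   and dissolution of segments <30 ms via global map dissimilarity
   `GMD = √(2(1−|corr|))`;
5. per-subject temporal parameters and statistics — pooled-variance
   t-tests across groups, Spearman correlations with smoking
   characteristics inside the smoker group.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
import microstatekit as mk

cfg = mk.PipelineConfig()          # study defaults: 25+25 subjects, 300 s, snr 4
res = mk.run_simulation_study(cfg)

print(res.prototypes.labels, round(res.prototypes.gev, 3))
tests = res.group_tests.set_index("parameter")
print(tests.loc[["occurrence_C", "duration_D"], ["t", "df", "p"]])
corr = res.correlations
print(corr[(corr.variable == "FTND") & (corr.feature == "duration_D")])
```

prints (deterministically, about a minute on one CPU):

```
['A', 'B', 'C', 'D'] 0.973
                      t    df             p
parameter
occurrence_C -13.078580  48.0  1.937086e-17
duration_D     3.849817  48.0  3.493188e-04
   feature variable       rho        p  n
duration_D     FTND -0.670988 0.000241 25
```

Reading: the four prototypes explain 97.3 % of the GFP-weighted
topographic variance; the planted group effects are recovered with the
planted signs (smokers visit class C less often and dwell longer in
class D), and the planted negative FTND→D-duration coupling appears as a
significant negative Spearman correlation among the 25 smokers.

The same chain runs on recorded data
(`mk.run_on_recordings([...paths...], "clinical.csv", cfg)`, EDF or
BrainVision), and from the shell:

```bash
microstatekit run-all --seed 0 --out out/        # simulate + full analysis
microstatekit simulate --seed 0 --out cohort/    # cohort only (HDF5 + CSVs)
microstatekit preprocess --in sub-01.vhdr --out sub-01.h5
```

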