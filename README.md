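# gazehmm

Bayesian hidden-Markov-model analysis of gaze scanpaths on social
scenes: data-driven regions of interest, transition and fixation
variables, and mixed-effects group comparison.

## The problem

Classical eye-tracking analyses quantify how long viewers look at
hand-drawn boxes.  When the question is *social* perception — e.g.
whether children on the autism spectrum link the faces in a scene less
than typically developing controls — the interesting signal is dynamic:
how gaze moves *between* informative regions, and how likely those links
are.  `gazehmm` implements that analysis for researchers working with
fixation-level eye-tracking data:

1. **Data-driven ROIs.**  Fixations (x, y, duration) are modelled by a
   hidden Markov model whose K hidden states are 3-D Gaussians — spatial
   ellipses with a characteristic fixation duration.  Learning is
   variational Bayesian EM with conjugate priors (Dirichlet on the
   initial vector and each transition row, Normal-Wishart on each
   emission), so the evidence lower bound (ELBO) both drives fitting and
   selects K.
2. **Two-step group modelling.**  Step 1 learns one representative model
   per stimulus from all participants; Step 2 fits each participant an
   individual model with K fixed and state identities tied to the
   representative ROIs, so transition parameters are comparable across
   participants.
3. **Gaze variables.**  States are labelled face / body / nonsocial (one
   sparse catch-all state is excluded); per participant and stimulus the
   package derives transition counts and model-based transition
   probabilities for five ROI pairs, fixation and visit counts per
   category, total fixation duration and total transition count.
4. **Statistics.**  Each variable is compared between groups with

       value ~ 1 + group + actors + group:actors + covariate_c + (1 | participant)

   (REML, mean-centred covariate, estimated marginal means, contrasts vs
   the TD reference at alpha = 0.05).

Because no such clinical data set is publicly deposited, the package
ships a first-class synthetic cohort generator (three groups 25/15/12,
2 + 2 recordings of 120 s, 12- and 9-ROI scene templates, lognormal
durations) that plants a group effect only in transition structure —
face-to-face linking probability 0.30 vs 0.22 — providing ground truth
for every recovery, specificity and calibration test.  See
`docs/methods.md` for the full model description and design rationale.

## Worked example

```python
import gazehmm

# a synthetic cohort with the planted face-face effect (TD vs ASD+ADHD)
data = gazehmm.simulate_cohort(group_sizes={"TD": 25, "ASD_ADHD": 15},
                               seed=7, recordings_per_class=2)
cfg = gazehmm.PipelineConfig(seed=7, restarts=5, elbo_rel_tol=1e-5)
res = gazehmm.run_pipeline(cfg, data.scanpaths, data.cohort, data.stimuli,
                           templates=data.templates,
                           k_range_per_class={"four_actor": [12],
                                              "one_actor": [9]})

vt = res.variable_table
ff = vt[(vt.variable == "transition_probability")
        & (vt.category == "face_face") & (vt.actors == "four_actor")]
print(ff.groupby("group").value.mean())
rep = res.stats_report.set_index(["variable", "category"])
print(rep.loc[("transition_probability", "face_face"),
              ["F_group", "p_TD_vs_ASD_ADHD"]])
```

Output from this exact run:

```
group
ASD_ADHD    0.210948
TD          0.291709
Name: value, dtype: float64
F_group             30.661930
p_TD_vs_ASD_ADHD     0.000002
Name: (transition_probability, face_face), dtype: float64
```

The pipeline recovers the planted face-to-face linking probabilities
almost exactly (measured 0.29 vs 0.21 against truth 0.30 vs 0.22; the
small downward shift is the documented shrinkage of model-based
estimates), and the mixed-model contrast against TD is highly
significant, while body-body and nonsocial-nonsocial contrasts stay
null.

The same stages are scriptable from a shell:

```
gazehmm simulate --seed 7 --out-dir sim/
gazehmm run sim/fixations.csv sim/cohort.csv sim/stimuli.csv \
        --seed 7 --out-dir results/
```

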