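# remap3d

Structure-augmented one-class collaborative filtering for genome-scale drug
off-target prediction, with the surrounding analytics a repurposing study
needs: activity-record standardization, a binding-site/docking screen that
imputes putative off-targets, dose-response curve fitting (Kd, EC50, IC50,
GI50, activity area), kinome-panel evaluation, and drug-sensitivity gene
statistics.

## The problem

Chemical-genomics databases record hundreds of thousands of positive
drug-protein associations, but the matrix of drugs x proteins is extremely
sparse and *positive-only*: an absent entry means "never assayed", not
"inactive". Predicting which unobserved cells are real interactions — a
drug's off-targets — is a one-class matrix-completion problem. `remap3d`
augments the observed matrix with structure-derived evidence (binding-site
similarity to a template pocket plus protein-ligand docking) before
factorizing, so that proteins never co-assayed with a drug can still
receive informed scores.

## The model

Let `R` (n x m) hold observed positive chemical-protein associations,
`Q` hold structure-screen imputations in unobserved cells (disjoint from
`R`), and `C`, `T` be chemical-chemical and protein-protein similarity
graphs with degree matrices `D_C`, `D_T`. Nonnegative rank-r factors
`U` (n x r) and `V` (m x r) minimize

    sum_{i,j} w_ij (R_ij + Q_ij - U_i . V_j)^2
      + alpha (||U||_F^2 + ||V||_F^2)
      + beta  tr(U' (D_C - C) U)
      + gamma tr(V' (D_T - T) V)

where the sum runs over **all** cells with class-dependent confidence
weights: `w_obs` on observed entries, `w_imp` on imputed entries, and a
small `w_zero` on the remaining cells (whose target is 0, or a fixed
uniform imputation value in the baseline mode). The graph terms pull
similar chemicals (proteins) toward similar latent factors. Prediction
scores are `P = U V'`; a drug's off-target candidates are the top-ranked
proteins of its row. The optimizer is a graph-regularized weighted
multiplicative-update scheme whose dense low-weight background is handled
implicitly (one iteration costs `O(nnz*r + (n+m)*r^2)`).

Activity records are standardized before matrix assembly: IC50 <= 10 µM,
Ki <= 5 µM or pKi >= 5 count as active; percent-inhibition readouts
convert via `Ki = conc * (100 - %inh) / %inh`; records with a curation
confidence below 9 are dropped.

## Worked example

The packaged fixture is the structure screen of a PDE3B template pocket
(PDB 1SO2) against twenty candidate human structures, docked with five
PDE3-inhibitor drugs. Filtering at binding-site p-value < 2.0e-3 and
docking score < -7.5 (both strict):

```python
>>> import remap3d as r3
>>> hits, docks = r3.load_pde3b_screen()
>>> pairs = r3.filter_offtarget_candidates(hits, docks)
>>> sum(1 for chem, prot in pairs if chem == "levosimendan")
16
>>> ("levosimendan", "Q9BRS2") in pairs   # the RIOK1 structure 4OTP, score -7.6
True
```

The 16 surviving levosimendan pairs become the imputation matrix `Q`
(`r3.build_imputation_matrix(pairs)`), feeding the solver alongside `R`.

Fitting a competition-binding curve for the levosimendan-RIOK1
interaction (12-point half-log dilution from 100 µM, noise-free at the
measured constant):

```python
>>> doses = r3.half_log_doses(100.0, 12)
>>> y = r3.hill_response(doses, background=0.0, signal=100.0, kd=0.82)
>>> r3.fit_hill(r3.DoseResponseCurve(tuple(doses), tuple(y))).kd
0.8200000007496172
```

i.e. the fitter returns the dissociation constant Kd = 0.82 µM that
generated the curve. The same pattern with `fit_sigmoid` on a viability
curve returns the midpoint C (EC50); `derive_response_parameters` then
yields IC50 (concentration at half the upper limit) and GI50
(half-maximal growth inhibition relative to the time-zero cell count).

Everything is also reachable from the `remap3d` command line:
`simulate`, `build-matrix`, `screen`, `fit`, `rank`, `evaluate`,
`doseresponse`, `sensitivity`, `config`.

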