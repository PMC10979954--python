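"""Orthogonalized PLS regression of cytokine levels on age.

Builds a disease cohort whose three planted cytokines (MIP-1a, MIP-1b, KC)
rise with age, selects the number of latent variables by 100-repeat
cross-validation (k = 5 folds since n < 30), orthogonalizes the model so all
predictive covariance sits on LV1, reports the VIP > 1 signature, and tests
significance with a permutation Z test.
"""

from cytoconn import cyto_clean, pls, synth

cfg = synth.SynthConfig(n_subjects_per_group=7, n_rois=8, n_systems=4,
                        affected_systems=(0, 1), seed=2)
panel = synth.gen_cytokine_panel(cfg, n_subjects_per_genotype=26)
panel = cyto_clean.censor(panel)
panel, _ = cyto_clean.retain_analytes(panel)

X, meta = cyto_clean.panel_to_wide(panel, genotype="5xFAD")
y = meta["age_months"].to_numpy(float)

cv = pls.cross_validate(X.to_numpy(), y, repeats=100, seed=1)
print(f"n = {len(y)} subjects, k = {cv.k} folds; "
      f"mean RMSECV per LV count {dict(zip(cv.candidates, cv.mean_statistic.round(3)))}")
print(f"chosen number of latent variables: {cv.chosen_A}")

model = pls.fit_pls(X.to_numpy(), y, cv.chosen_A, names=list(X.columns))
om = pls.orthogonalize(model)
sig = pls.signature_report(om)
print("\ncytokines with VIP > 1 (signed LV1 loading):")
print(sig.to_string(index=False))

perm = pls.permutation_test(X.to_numpy(), y, cv.chosen_A, n_perm=200,
                            cv_repeats=5, seed=4)
print(f"\npermutation test: Z = {perm.z:.2f}, p = {perm.p:.2e} "
      f"({perm.n_permutations} permutations)")
print("The three planted analytes top the VIP ranking with positive loadings")
print("(up with age). The observed RMSECV sits below the permutation null;")
print("note the Z test is conservative because the null RMSECV distribution")
print("is right-skewed.")
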