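"""Fixed- and random-effects RSA between visual and linguistic cohorts.

Generates two 12-subject behavioral cohorts that share a common geometry
but carry modality-unique structure and noise, then compares them the two
standard ways: once on subject-averaged RDMs (fixed effects) and once by
averaging all cross-subject pairwise correlations with a permutation test
(random effects).
"""
from marsa.rdm import fixed_effects_rsa, random_effects_rsa, within_modality_consistency
from marsa.synthetic import TwoModalitySpec, make_ground_truth, simulate_two_modalities

gt = make_ground_truth(n_items=30, n_dims=3, n_categories=4, cat_separation=2.0, seed=12)
spec = TwoModalitySpec(
    shared_w=1.0, unique_visual_w=0.3, unique_linguistic_w=0.3, noise_sd=0.3, seed=5
)
visual, linguistic, _ = simulate_two_modalities(gt, spec, n_subjects=12)

rho_fe = fixed_effects_rsa(visual, linguistic)
rho_re, p = random_effects_rsa(visual, linguistic, n_perm=999, seed=0)
print(f"fixed-effects Spearman (averaged RDMs):   rho = {rho_fe:.3f}")
print(f"random-effects Spearman (subject pairs):  rho = {rho_re:.3f}, p = {p:.4f}")
print(f"within-visual consistency:                rho = {within_modality_consistency(visual):.3f}")
print(f"within-linguistic consistency:            rho = {within_modality_consistency(linguistic):.3f}")
print(
    "\nAveraging before correlating cancels subject noise, so the fixed-effects\n"
    "coefficient exceeds the mean single-subject-pair correlation; both are\n"
    "driven by the planted shared geometry."
)
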