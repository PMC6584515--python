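"""Compare smoothing methods by repeated cross-validation.

On a fixture whose negatives form their own community coupled to the
positive one (so the negative labels carry real information), SINKSOURCE
should beat SINKSOURCE+ — which discards the negatives — at every lambda.
The comparison uses 10 repeats of stratified 5-fold CV (50 AUCs each) and
a one-tailed Welch's t-test.
"""

from pdprank import (
    FixtureSpec,
    LabelAssignment,
    cross_validate,
    make_fixture,
    make_smoother,
    welch_t_test,
)

fx = make_fixture(FixtureSpec.disease_like(seed=3))
labels = LabelAssignment(fx.positives, fx.negatives, fx.graph)

ss = cross_validate(make_smoother("sinksource"), labels, k=5, repeats=10, seed=5)
print(f"SINKSOURCE        : mean AUC {ss.mean_auc:.3f} "
      f"(sd {ss.std_auc:.3f}, {len(ss.aucs)} folds)")

for lam in (0.01, 1.0, 10.0, 50.0):
    ssp = cross_validate(
        make_smoother("sinksource+", lam=lam), labels, k=5, repeats=10, seed=5
    )
    t, p = welch_t_test(ss.aucs, ssp.aucs, alternative="greater")
    star = " *" if p < 0.01 else ""
    print(
        f"SINKSOURCE+ l={lam:<5g}: mean AUC {ssp.mean_auc:.3f}   "
        f"Welch t={t:+.2f}, one-tailed p={p:.2g}{star}"
    )

print(
    "\nStars mark p < 0.01: dropping informative negative labels costs "
    "accuracy at every\nlambda on this world; the sink alone cannot replace "
    "curated negatives."
)
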