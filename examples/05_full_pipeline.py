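"""The whole pipeline in one call: synthetic epochs -> TQWT subbands ->
eleven features -> ANOVA top-6 -> PNN bandwidth grid -> 5-fold CV report,
with the chance-level control alongside."""

from tqeeg import SyntheticSpec, generate, run_pipeline

for sep, label in [(1.0, "separable classes"), (0.0, "null (identical classes)")]:
    epochs = generate(SyntheticSpec(n_per_class=10, n_channels=4, seed=4,
                                    separability=sep))
    result = run_pipeline(epochs, Q=1, r=3, J=8, seed=4, honest_selection=True)
    best = result.report.best["pnn"]
    print(f"{label}: best mean accuracy {best['acc_mean']:.1f}% at {best['params']}, "
          f"selected {', '.join(result.ranking.selected)}")
# With distinct band-power profiles the pipeline recovers the six classes
# nearly perfectly; with identical profiles accuracy sits at chance (~16.7%),
# confirming the evaluation is leakage-free (selection refit per fold).
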