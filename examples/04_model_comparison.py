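"""RSS/AIC model comparison from the published EMT-6 residual table.

Feeds the published per-arm residual sums of squares of the two model
variants (constant ϵ fitted per arm, k=1 each and 6 globally; dynamic ϵ
fitted jointly, k=5) through the AIC bookkeeping and prints the per-arm
and global comparison table.
"""

from pdl1dyn import EMT6_REFERENCE_RSS, FitResult, ModelVariant, comparison_table, format_table


def fit_from_published(variant: str, k: int) -> FitResult:
    per_rss = EMT6_REFERENCE_RSS[variant]
    return FitResult(
        variant=ModelVariant(variant),
        params={},
        bounds={},
        per_therapy_rss=dict(per_rss),
        n_per_therapy={tid: 6 for tid in per_rss},
        k=k,
        converged=True,
        n_restarts=0,
        seed=None,
    )


rows = comparison_table(fit_from_published("constant", k=1), fit_from_published("dynamic", k=5))
print(format_table(rows))
print(
    "\nReading: the constant-ϵ variant is preferred on every arm and globally\n"
    "(AIC 259.84 vs 268.75); the dynamic-ϵ variant achieves the lower RSS on\n"
    "the Avelumab monotherapy arm (d) but its five shared parameters cost it\n"
    "on AIC. Both variants encode therapy-dependent PD-L1 expression, which\n"
    "is the central scientific claim."
)
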