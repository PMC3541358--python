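"""Compare transgenic expression profiles of one enhancer between species.

Builds three small profile pairs — one globally divergent, one partially
divergent, one identical — and prints the divergence metrics.
"""

from cnediv import ExpressionProfile, compare_profiles, summarize_dataset


def pair(cne, mouse, zebrafish):
    return (
        ExpressionProfile(cne, "mouse", "transgenic", frozenset(mouse)),
        ExpressionProfile(cne, "zebrafish", "transgenic", frozenset(zebrafish)),
    )


pairs = [
    pair("enh_global", {"DRG", "spinal cord"}, {"forebrain"}),
    pair("enh_partial", {"hindbrain", "spinal cord"}, {"spinal cord"}),
    pair("enh_identical", {"forebrain"}, {"forebrain"}),
]

results = [compare_profiles(m, z) for m, z in pairs]
for res in results:
    print(
        f"{res.cne_id}: shared={sorted(res.shared) or '-'} "
        f"mouse_only={sorted(res.mouse_only) or '-'} "
        f"zebrafish_only={sorted(res.zebrafish_only) or '-'} "
        f"fraction={res.fraction:.2f} -> {res.category}"
    )

summary = summarize_dataset(results, [p for mz in pairs for p in mz])
print(
    f"\n{summary.n_cnes} enhancers: {summary.n_any_specific} with a "
    f"species-specific domain, {summary.n_global} global, "
    f"{summary.n_identical} identical"
)
# The fraction is the share of species-specific domains among all domains
# active in either species; >= 0.75 counts as a global pattern change.
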