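"""Dual-reporter normalization, lineage ratios, and construct comparisons.

Simulates three constructs — wildtype, a weak variant (30% strength), and a
variant attenuated 2-fold in the secondary lineage — across replicates
with strong per-embryo electroporation-efficiency noise, then shows that
the reporter/control ratio cancels the efficiency, per-replicate wildtype
normalization anchors the scale, and pooled t-tests with BH adjustment
flag the differences.
"""

from cisquant import (
    ConstructSpec,
    ExpressionSimConfig,
    normalize_experiment,
    pairwise_tests,
    simulate_measurements,
)
from cisquant.reporter import tests_to_frame

cfg = ExpressionSimConfig(
    constructs=[
        ConstructSpec("WT"),
        ConstructSpec("WEAK", strength=0.3),
        ConstructSpec("SEC", secondary_attenuation=0.5),
    ],
    n_embryos=30,
    n_replicates=3,
    efficiency_sigma=1.0,
    seed=11,
)
table, truth = simulate_measurements(cfg)
eff = truth.efficiencies["efficiency"]
print(f"{len(table)} embryos; efficiency spans "
      f"{eff.min():.2f}x to {eff.max():.2f}x across embryos")

norm = normalize_experiment(table, "WT")
summary = norm.groupby("construct_id")[
    ["normalized_ratio", "primary_secondary_ratio"]
].agg(["mean", "median"]).round(3)
print("\nper-construct summary (wildtype mean is 1 by construction):")
print(summary)

groups = {c: g["normalized_ratio"].to_numpy() for c, g in norm.groupby("construct_id")}
print("\npairwise pooled t-tests, Benjamini-Hochberg adjusted:")
print(tests_to_frame(pairwise_tests(groups)).round(4).to_string(index=False))
print("\nWEAK recovers its simulated 0.3 strength; SEC shows a")
print("primary/secondary ratio near 2 (its reporter is halved only in the")
print("8 posterior secondary-lineage cells) while its whole-notochord")
print("level stays near wildtype.")
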