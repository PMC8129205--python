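"""Morphometric comparison of three synthetic neuron cohorts.

Three cohorts of ten neurons emulate domain-specific projection neurons
that differ in branching density and tortuosity.  Each neuron is trimmed
to a 300-unit Euclidean radius, LOESS-smoothed, profiled with classic and
surface-area Sholl analyses, and summarized by L-Measure-style features;
cohorts are compared with PCA, pairwise Wilcoxon rank-sum tests under
BH-FDR, and persistence-diagram Wasserstein distances.  Writes
results/morpho_features.csv, results/morpho_stats.csv,
results/sholl_classic.csv, results/pca_scores.csv and
results/persistence_group_distances.csv.

Finding: the planted bifurcation-rate and tortuosity differences surface
as FDR-significant n_bifurcations / tortuosity contrasts; in the
persistence summary the heavily branched caudal cohort sits farthest from
the sparse medial one (between-group mean well above the medial
within-group mean), mirroring the PCA separation.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tracemap import morpho, persistence, stats, synth

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

COHORTS = {
    # sparser, straighter arbors vs denser and more tortuous ones
    "medial": dict(bifurcation_rate=0.005, tortuosity_target=1.10),
    "lateral": dict(bifurcation_rate=0.007, tortuosity_target=1.15),
    "caudal": dict(bifurcation_rate=0.010, tortuosity_target=1.25),
}
N_PER_GROUP = 10


def build_cohorts():
    neurons = []
    for g, (name, knobs) in enumerate(COHORTS.items()):
        for k in range(N_PER_GROUP):
            spec = synth.NeuronSpec(n_stems=3, seed=1000 * g + k, **knobs)
            n = synth.gen_neuron(spec)
            n = morpho.loess_smooth(morpho.trim(n, radius=300.0))
            n.group_label = name
            neurons.append(n)
    return neurons


def main():
    neurons = build_cohorts()

    table = morpho.feature_table(neurons)
    table.to_csv(OUT / "morpho_features.csv", index=False)

    radii = np.arange(10.0, 210.0, 10.0)
    sholl = pd.DataFrame(
        {f"n{k}": morpho.sholl_classic(n, radii) for k, n in enumerate(neurons)},
        index=radii,
    )
    sholl.to_csv(OUT / "sholl_classic.csv", index_label="radius")

    emb = morpho.pca_embed(table.drop(columns="group"))
    scores = emb.scores.assign(group=table["group"].to_numpy())
    scores.to_csv(OUT / "pca_scores.csv", index=False)
    print(
        "PCA explained variance:",
        np.round(emb.explained_variance_ratio, 3),
    )

    res = stats.pairwise_wilcoxon_fdr(table.drop(columns="group"), table["group"])
    res.to_csv(OUT / "morpho_stats.csv", index=False)
    sig = res[res["significant"]]
    print(f"{len(sig)} FDR-significant feature contrasts:")
    for _, row in sig.iterrows():
        print(
            f"  {row.feature}: {row.group1} vs {row.group2} "
            f"(W={row.W:.1f}, p_adj={row.p_adj:.4f}, "
            f"shift [{row.ci_low:.3g}, {row.ci_high:.3g}])"
        )

    diagrams = [persistence.persistence_diagram(n) for n in neurons]
    _, summary = persistence.group_distance_summary(
        diagrams, [n.group_label for n in neurons]
    )
    summary.to_csv(OUT / "persistence_group_distances.csv", index=False)
    print("\npersistence Wasserstein distances (group means):")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
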