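"""Statistical calibration of the two tests on abundance-level panels.

Measures type-I error of the MPV contrast and the interaction ANOVA on
null panels, and estimation bias / classifier sensitivity on panels with
injected effects, at the study's replicate structure (n = 3).

Usage: python analysis/06_calibration.py [--out results/calibration.tsv] [--seed 0]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from heterosol.nonadditive import HYBRID_VS_MPV, classify, mpv_contrast
from heterosol.simulate import simulate_abundance_panel
from heterosol.solubility import analyze_solubility, interaction_anova


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/calibration.tsv"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    rows = []

    m, d = simulate_abundance_panel(10_000, delta=0.0, residual_sd=0.3,
                                    seed=args.seed)
    res = mpv_contrast(m, d, "hybrid1", ("parent1", "parent2"))
    rows.append(("mpv_type_i_error",
                 (res.loc[res["contrast"] == HYBRID_VS_MPV, "p"] <= 0.05).mean(),
                 10_000))

    matrices, design = simulate_abundance_panel(
        10_000, soluble_share_parent=0.5, soluble_share_hybrid=0.5,
        residual_sd=0.3, seed=args.seed + 1,
    )
    anova = interaction_anova(matrices, design, "hybrid1", ("parent1", "parent2"))
    rows.append(("interaction_type_i_error",
                 (anova["p_interaction"] <= 0.05).mean(), 10_000))

    delta = np.where(np.arange(1000) % 2 == 0, 1.0, -1.0)
    m, d = simulate_abundance_panel(1000, delta=delta, residual_sd=0.3,
                                    seed=args.seed + 2)
    res = mpv_contrast(m, d, "hybrid1", ("parent1", "parent2"))
    mpv = res[res["contrast"] == HYBRID_VS_MPV].set_index("orthogroup_id")
    mpv = mpv.reindex([f"P{i:05d}" for i in range(1000)])
    rows.append(("log2fc_mean_bias",
                 float(np.mean(mpv["log2FC"].to_numpy() - delta)), 1000))
    cls = classify(mpv.reset_index())["class"].to_numpy()
    rows.append(("nonadditive_sensitivity",
                 float((cls == np.where(delta > 0, "up", "down")).mean()), 1000))

    share_hyb = np.where(np.arange(1000) < 500, 0.73, 0.5)
    matrices, design = simulate_abundance_panel(
        1000, soluble_share_parent=0.5, soluble_share_hybrid=share_hyb,
        residual_sd=0.2, seed=args.seed + 3,
    )
    sol = analyze_solubility(
        matrices, design, "hybrid1", ("parent1", "parent2")
    ).set_index("orthogroup_id").reindex([f"P{i:05d}" for i in range(1000)])
    rows.append(("solubility_sensitivity",
                 float((sol.iloc[:500]["class"] == "more_soluble_hybrid").mean()),
                 500))
    rows.append(("solubility_false_shift_rate",
                 float((sol.iloc[500:]["class"] != "no_shift").mean()), 500))

    table = pd.DataFrame(rows, columns=["quantity", "value", "n"])
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
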