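"""Solubility shifts between hybrids and parents.

Runs the fraction x genotype interaction ANOVA and the solubility score
(mid-parent median soluble:insoluble ratio minus the hybrid's) on the
soluble/insoluble abundance matrices, classifies shifts at |score| >= 0.5
and p <= 0.05, and scores calls against the injected truth.

Usage: python analysis/04_solubility.py [--outdir results/cohort]
"""

import argparse
from pathlib import Path

import pandas as pd

from heterosol import RunConfig
from heterosol.pipeline import stage_solubility


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    cfg = RunConfig.from_yaml(args.outdir / "config.yaml")
    stage_solubility(cfg, args.outdir)

    sol = pd.read_csv(args.outdir / "solubility.tsv", sep="\t")
    truth = pd.read_csv(args.outdir / "truth.tsv", sep="\t")
    merged = sol.merge(truth, on="orthogroup_id")
    label_map = {
        "more_soluble_hybrid": "more_soluble_hybrid",
        "more_soluble_parent": "more_soluble_parents",
    }
    for hyb, sub in merged.groupby("hybrid"):
        called = (sub["class"] != "no_shift").sum()
        injected = sub["true_solubility_class"] != "none"
        correct = (
            sub["class"] == sub["true_solubility_class"].map(label_map)
        )
        print(
            f"{hyb}: {called} shifted proteins of {len(sub)} complete; "
            f"correct direction for {correct[injected].mean():.2f} of injected, "
            f"false-shift rate {(sub.loc[~injected, 'class'] != 'no_shift').mean():.3f}"
        )


if __name__ == "__main__":
    main()
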