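"""Nonadditive protein expression: hybrid vs mid-parent value.

Fits the per-protein genotype model on the soluble-fraction abundances,
contrasts each hybrid against the mean of the parental means, classifies
proteins with |log2FC| >= 0.5 and uncorrected p <= 0.05 as up/down, and
scores the calls against the injected truth.

Usage: python analysis/03_nonadditive.py [--outdir results/cohort]
"""

import argparse
from pathlib import Path

import pandas as pd

from heterosol import RunConfig
from heterosol.nonadditive import HYBRID_VS_MPV
from heterosol.pipeline import stage_nonadditive


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    cfg = RunConfig.from_yaml(args.outdir / "config.yaml")
    stage_nonadditive(cfg, args.outdir)

    na = pd.read_csv(args.outdir / "nonadditive.tsv", sep="\t")
    truth = pd.read_csv(args.outdir / "truth.tsv", sep="\t")
    mpv = na[na["contrast"] == HYBRID_VS_MPV].merge(truth, on="orthogroup_id")
    for hyb, sub in mpv.groupby("hybrid"):
        up = (sub["class"] == "up").sum()
        down = (sub["class"] == "down").sum()
        injected = sub["true_nonadditive"] != "none"
        sens = (sub.loc[injected, "class"] != "additive/ns").mean()
        print(
            f"{hyb}: {up} up, {down} down of {len(sub)} testable proteins; "
            f"sensitivity for injected effects {sens:.2f}"
        )
    overlap = pd.read_csv(args.outdir / "nonadditive_overlap.tsv", sep="\t")
    for _, row in overlap.iterrows():
        print(
            f"  overlap {row['direction']}: {row['n_overlap']} shared of "
            f"{row['n_a']} ({row['hybrid_a']}) and {row['n_b']} ({row['hybrid_b']})"
        )


if __name__ == "__main__":
    main()
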