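"""Homoeolog-specific expression bias in hybrids and allopolyploids.

Within an orthogroup, peptides found in only one parent's homoeolog act as
reporters for that subgenome. Observed subgenome-specific peptide
occurrences are counted per orthogroup for each hybrid sample (run) and
pooled per genotype; a sample or genotype whose counts exceed a 3:1 ratio
(>75%, strict) toward one subgenome is called biased toward it. Biased
orthogroups are then intersected with the nonadditive up/down sets.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .nonadditive import HYBRID_VS_MPV

logger = logging.getLogger(__name__)

CALLS = ("parent1_biased", "parent2_biased", "unbiased")


def count_subgenome_peptides(
    features: pd.DataFrame,
    design: pd.DataFrame,
    kept_orthogroups: Iterable[str],
    target_genotypes: Iterable[str],
    intensity_weighted: bool = False,
) -> pd.DataFrame:
    """Per-orthogroup, per-sample subgenome-specific peptide counts.

    Counts observed peptide-run occurrences (presence-based; with
    ``intensity_weighted`` each occurrence contributes its linear
    intensity instead of 1). Shared peptides are excluded; only runs of
    ``target_genotypes`` (the hybrids/allopolyploids) are counted; only
    ``kept_orthogroups`` (survivors of the cross-match filter) appear.
    """
    kept = set(kept_orthogroups)
    targets = set(target_genotypes)
    run_geno = dict(zip(design["run_id"], design["genotype"]))

    f = features[
        features["subgenome_specific"].isin(("parent1", "parent2"))
        & features["run_id"].map(run_geno).isin(targets)
    ]
    excluded = set(f["orthogroup_id"]) - kept
    if excluded:
        logger.info(
            "bias counting skipped %d discarded orthogroups", len(excluded)
        )
    f = f[f["orthogroup_id"].isin(kept)]
    weight = f["intensity"].to_numpy() if intensity_weighted else 1.0
    tallies = (
        pd.DataFrame(
            {
                "orthogroup_id": f["orthogroup_id"].to_numpy(),
                "run_id": f["run_id"].to_numpy(),
                "subgenome": f["subgenome_specific"].to_numpy(),
                "w": weight,
            }
        )
        .groupby(["orthogroup_id", "run_id", "subgenome"])["w"]
        .sum()
        .unstack("subgenome", fill_value=0.0)
        .reindex(columns=["parent1", "parent2"], fill_value=0.0)
        .reset_index()
        .rename(columns={"parent1": "n_parent1", "parent2": "n_parent2"})
    )
    tallies["genotype"] = tallies["run_id"].map(run_geno)
    return tallies


def _call(n1: np.ndarray, n2: np.ndarray, threshold: float) -> np.ndarray:
    total = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, n1 / np.where(total > 0, total, 1.0), np.nan)
    call = np.full(n1.shape, "unbiased", dtype=object)
    call[np.nan_to_num(frac, nan=0.5) > threshold] = "parent1_biased"
    call[np.nan_to_num(frac, nan=0.5) < 1.0 - threshold] = "parent2_biased"
    return call


def classify_bias(
    counts: pd.DataFrame, threshold: float = 0.75
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strict >3:1 bias calls per sample and pooled per genotype.

    A call requires ``fraction_parent1`` strictly above ``threshold``
    (parent1) or strictly below ``1 - threshold`` (parent2); a 3:1 count
    ratio is exactly at the boundary and stays unbiased. Orthogroups with
    no specific-peptide observations are unbiased. Returns
    ``(per_sample, pooled)``.
    """
    per_sample = counts.copy()
    n1 = per_sample["n_parent1"].to_numpy(float)
    n2 = per_sample["n_parent2"].to_numpy(float)
    total = n1 + n2
    per_sample["fraction_parent1"] = np.where(total > 0, n1 / np.maximum(total, 1), np.nan)
    per_sample["call"] = _call(n1, n2, threshold)

    pooled = (
        counts.groupby(["orthogroup_id", "genotype"], as_index=False)[
            ["n_parent1", "n_parent2"]
        ].sum()
    )
    pn1 = pooled["n_parent1"].to_numpy(float)
    pn2 = pooled["n_parent2"].to_numpy(float)
    ptotal = pn1 + pn2
    pooled["fraction_parent1"] = np.where(ptotal > 0, pn1 / np.maximum(ptotal, 1), np.nan)
    pooled["call"] = _call(pn1, pn2, threshold)
    return per_sample, pooled


def intersect_bias_nonadditive(
    pooled: pd.DataFrame, classified_contrasts: pd.DataFrame
) -> pd.DataFrame:
    """Overlap of biased orthogroups with the nonadditive up/down sets.

    Both inputs must cover the same orthogroup universe (the intersection
    must be non-empty when both are non-empty). Reports, per hybrid
    genotype, the nonadditive set sizes, how many of each are biased, and
    the proportion of the nonadditive set that is biased (NaN when the
    nonadditive set is empty).
    """
    mpv = classified_contrasts[
        classified_contrasts["contrast"] == HYBRID_VS_MPV
    ]
    if not mpv.empty and not pooled.empty:
        if not (set(mpv["orthogroup_id"]) & set(pooled["orthogroup_id"])):
            raise ValueError(
                "bias and contrast results share no orthogroups; "
                "were they computed on the same universe?"
            )
    rows = []
    for hyb, sub in mpv.groupby("hybrid"):
        biased = set(
            pooled.loc[
                (pooled["genotype"] == hyb) & (pooled["call"] != "unbiased"),
                "orthogroup_id",
            ]
        )
        up = set(sub.loc[sub["class"] == "up", "orthogroup_id"])
        down = set(sub.loc[sub["class"] == "down", "orthogroup_id"])
        nonadd = up | down
        rows.append(
            {
                "genotype": hyb,
                "n_biased": len(biased),
                "n_up": len(up),
                "n_down": len(down),
                "n_up_biased": len(up & biased),
                "n_down_biased": len(down & biased),
                "prop_nonadditive_biased": (
                    len(nonadd & biased) / len(nonadd) if nonadd else np.nan
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genotype",
            "n_biased",
            "n_up",
            "n_down",
            "n_up_biased",
            "n_down_biased",
            "prop_nonadditive_biased",
        ],
    )
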