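"""Mid-parent-value contrasts: nonadditive protein expression in hybrids.

For each protein (orthogroup) a fixed-effects group-means linear model on
log2 abundance is fit across the three genotypes of one fraction, and the
hybrid mean is contrasted against the mean of the two parental means
(weights 1, -1/2, -1/2). The standard error comes from the pooled residual
variance; the two-sided p-value from the t distribution with the residual
degrees of freedom. Following the source convention, p-values are left
uncorrected (an optional Benjamini-Hochberg column is available) and a
protein is called nonadditive when |log2FC| >= 0.5 and p <= 0.05.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

HYBRID_VS_MPV = "hybrid_vs_mpv"
PARENT1_VS_PARENT2 = "parent1_vs_parent2"


def _genotype_arrays(matrix: pd.DataFrame, design: pd.DataFrame, genotypes):
    """Per-genotype value arrays (proteins x replicates), NaN-padded."""
    run_geno = dict(zip(design["run_id"], design["genotype"]))
    arrays = {}
    for g in genotypes:
        cols = [c for c in matrix.columns if run_geno.get(c) == g]
        if not cols:
            raise ValueError(f"design error: no runs for genotype {g!r}")
        arrays[g] = matrix[cols].to_numpy(float)
    return arrays


def mpv_contrast(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    hybrid_genotype: str,
    parent_genotypes: tuple[str, str],
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Hybrid-vs-MPV and parent-vs-parent contrasts for every protein.

    ``matrix`` is a protein x run log2-abundance frame restricted to one
    fraction. Proteins with fewer than ``min_replicates`` non-missing
    values in any of the three genotypes are omitted. Returns a tidy frame
    with one row per protein and contrast.
    """
    p1, p2 = parent_genotypes
    arrays = _genotype_arrays(matrix, design, (hybrid_genotype, p1, p2))
    h, a, b = arrays[hybrid_genotype], arrays[p1], arrays[p2]

    def stats(x):
        mask = ~np.isnan(x)
        n = mask.sum(axis=1)
        m = np.where(mask, x, 0.0).sum(axis=1) / np.maximum(n, 1)
        m = np.where(n > 0, m, np.nan)
        with np.errstate(invalid="ignore"):
            sse = np.where(mask, (x - m[:, None]) ** 2, 0.0).sum(axis=1)
        return n, m, sse

    nh, mh, sh = stats(h)
    n1, m1, s1 = stats(a)
    n2, m2, s2 = stats(b)

    ok = (nh >= min_replicates) & (n1 >= min_replicates) & (n2 >= min_replicates)
    N = nh + n1 + n2
    df = N - 3
    sse = sh + s1 + s2
    with np.errstate(divide="ignore", invalid="ignore"):
        s2res = sse / df

    rows = []
    for name, est, w in (
        (HYBRID_VS_MPV, mh - (m1 + m2) / 2.0, 1.0 / nh + 0.25 / n1 + 0.25 / n2),
        (PARENT1_VS_PARENT2, m1 - m2, 1.0 / n1 + 1.0 / n2),
    ):
        with np.errstate(invalid="ignore"):
            se = np.sqrt(s2res * w)
            tstat = est / np.where(se > 0, se, 1.0)
            # zero residual variance: p degenerates to 0 unless the
            # contrast itself is exactly zero
            p = np.where(
                se > 0,
                2.0 * t_dist.sf(np.abs(np.nan_to_num(tstat)), np.maximum(df, 1)),
                np.where(est == 0.0, 1.0, 0.0),
            )
        frame = pd.DataFrame(
            {
                "orthogroup_id": matrix.index,
                "hybrid": hybrid_genotype,
                "contrast": name,
                "log2FC": est,
                "se": se,
                "p": p,
                "df": df,
                "n_hybrid": nh,
                "n_parent1": n1,
                "n_parent2": n2,
            }
        )
        rows.append(frame[ok])
    return pd.concat(rows, ignore_index=True)


def classify(
    results: pd.DataFrame,
    lfc_threshold: float = 0.5,
    p_threshold: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Attach the up / down / additive-ns class (thresholds inclusive)."""
    out = results.copy()
    p = out["p"].to_numpy(float)
    if adjust:
        out["p_adj"] = benjamini_hochberg(p)
        p = out["p_adj"].to_numpy(float)
    lfc = out["log2FC"].to_numpy(float)
    cls = np.full(len(out), "additive/ns", dtype=object)
    cls[(lfc >= lfc_threshold) & (p <= p_threshold)] = "up"
    cls[(lfc <= -lfc_threshold) & (p <= p_threshold)] = "down"
    out["class"] = cls
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def classify_and_summarize(
    results: pd.DataFrame,
    lfc_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, set[str]], dict[str, set[str]], pd.DataFrame]:
    """Classify MPV contrasts and tabulate per-hybrid up/down sets plus
    pairwise overlaps across hybrids (Venn-style counts).

    Returns ``(classified, up_sets, down_sets, overlap_table)``.
    """
    classified = classify(results, lfc_threshold, p_threshold)
    mpv = classified[classified["contrast"] == HYBRID_VS_MPV]
    up: dict[str, set[str]] = {}
    down: dict[str, set[str]] = {}
    for hyb, sub in mpv.groupby("hybrid"):
        up[hyb] = set(sub.loc[sub["class"] == "up", "orthogroup_id"])
        down[hyb] = set(sub.loc[sub["class"] == "down", "orthogroup_id"])
    rows = []
    for ha, hb in combinations(sorted(up), 2):
        for direction, sets in (("up", up), ("down", down)):
            rows.append(
                {
                    "hybrid_a": ha,
                    "hybrid_b": hb,
                    "direction": direction,
                    "n_a": len(sets[ha]),
                    "n_b": len(sets[hb]),
                    "n_overlap": len(sets[ha] & sets[hb]),
                }
            )
    overlap = pd.DataFrame(
        rows, columns=["hybrid_a", "hybrid_b", "direction", "n_a", "n_b", "n_overlap"]
    )
    return classified, up, down, overlap
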