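"""Protein solubility shifts between hybrids and their parents.

Two complementary quantities are computed per protein from the soluble and
insoluble fraction abundances:

* **interaction ANOVA** — a two-way ANOVA on log2 abundance with factors
  fraction (soluble/insoluble) and genotype (progenitors pooled vs hybrid)
  plus their interaction; a significant interaction means the soluble:
  insoluble partitioning differs between hybrid and parents.
* **solubility score** — per replicate the linear-scale soluble/insoluble
  abundance ratio is formed; per genotype the median ratio over replicates
  is taken (medians because the insoluble fraction is noisy); the score is

      score = mean(median_p1, median_p2) - median_hybrid

  so a positive score means the protein is more soluble in the parents.

A protein is classified ``more_soluble_parents`` when p <= 0.05 and score
>= 0.5, ``more_soluble_hybrid`` when p <= 0.05 and score <= -0.5, else
``no_shift``. Only proteins quantified in every replicate of both
fractions for all three genotypes enter either computation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

logger = logging.getLogger(__name__)

CLASSES = ("more_soluble_parents", "more_soluble_hybrid", "no_shift")


def _complete_block(
    matrices: dict[str, pd.DataFrame],
    design: pd.DataFrame,
    genotypes: tuple[str, ...],
):
    """Stack soluble+insoluble values into (proteins x cells) with a fixed
    cell layout; returns (proteins, Y, cells) keeping complete rows only.

    Each cell is one (fraction, genotype, replicate) run.
    """
    run_info = design.set_index("run_id")
    cells = []  # (fraction, genotype, replicate, matrix, column)
    for fraction in ("soluble", "insoluble"):
        if fraction not in matrices:
            raise ValueError(f"missing {fraction} abundance matrix")
        m = matrices[fraction]
        for col in m.columns:
            if col not in run_info.index:
                continue
            g = run_info.loc[col, "genotype"]
            if g in genotypes:
                cells.append(
                    (fraction, g, int(run_info.loc[col, "replicate"]), col)
                )
    proteins = matrices["soluble"].index.intersection(matrices["insoluble"].index)
    Y = np.column_stack(
        [
            matrices[fr].reindex(proteins)[col].to_numpy(float)
            for fr, g, rep, col in cells
        ]
    )
    complete = ~np.isnan(Y).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "solubility completeness rule omitted %d proteins", n_dropped
        )
    return proteins[complete], Y[complete], [c[:3] for c in cells]


def interaction_anova(
    matrices: dict[str, pd.DataFrame],
    design: pd.DataFrame,
    hybrid_genotype: str,
    parent_genotypes: tuple[str, str],
) -> pd.DataFrame:
    """Per-protein fraction x genotype interaction test.

    The genotype factor has two levels: both parents pooled as
    "progenitors" vs the hybrid. The interaction F statistic compares the
    residual sums of squares of the additive model against the full
    cell-means model; with 2x2 cells the interaction has 1 degree of
    freedom and its test is invariant to the type of sums of squares.
    """
    genotypes = (*parent_genotypes, hybrid_genotype)
    proteins, Y, cells = _complete_block(matrices, design, genotypes)
    if len(proteins) == 0:
        return pd.DataFrame(columns=["orthogroup_id", "F_interaction", "p_interaction"])

    frac = np.array([1.0 if c[0] == "soluble" else 0.0 for c in cells])
    hyb = np.array([1.0 if c[1] == hybrid_genotype else 0.0 for c in cells])
    ones = np.ones(len(cells))
    X_add = np.column_stack([ones, frac, hyb])
    X_full = np.column_stack([ones, frac, hyb, frac * hyb])

    def rss(X):
        # residual quadratic form via the projection complement, shared
        # across proteins because the design is identical for every row
        Q, _ = np.linalg.qr(X)
        R = Y.T - Q @ (Q.T @ Y.T)
        return np.sum(R * R, axis=0)

    sse_add = rss(X_add)
    sse_full = rss(X_full)
    df_err = len(cells) - X_full.shape[1]
    if df_err <= 0:
        raise ValueError("not enough replicates for the interaction test")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (sse_add - sse_full) / (sse_full / df_err)
    F = np.clip(F, 0.0, None)
    p = np.where(sse_full > 0, f_dist.sf(F, 1, df_err), np.where(sse_add > sse_full, 0.0, 1.0))
    return pd.DataFrame(
        {"orthogroup_id": proteins, "F_interaction": F, "p_interaction": p}
    )


def solubility_score(
    matrices: dict[str, pd.DataFrame],
    design: pd.DataFrame,
    hybrid_genotype: str,
    parent_genotypes: tuple[str, str],
) -> pd.DataFrame:
    """Median soluble:insoluble ratios per genotype and the solubility score.

    Replicates are paired soluble<->insoluble by replicate index; ratios
    are taken on the linear scale (2**log2 abundance).
    """
    p1, p2 = parent_genotypes
    genotypes = (p1, p2, hybrid_genotype)
    proteins, Y, cells = _complete_block(matrices, design, genotypes)
    cols = {c: j for j, c in enumerate(cells)}

    medians = {}
    for g in genotypes:
        reps = sorted({rep for fr, geno, rep in cells if geno == g})
        ratios = []
        for rep in reps:
            s_key, i_key = ("soluble", g, rep), ("insoluble", g, rep)
            if s_key not in cols or i_key not in cols:
                raise ValueError(f"unpaired replicate {rep} for genotype {g}")
            ratios.append(np.exp2(Y[:, cols[s_key]] - Y[:, cols[i_key]]))
        medians[g] = np.median(np.column_stack(ratios), axis=1)

    ratio_mpv = (medians[p1] + medians[p2]) / 2.0
    score = ratio_mpv - medians[hybrid_genotype]
    return pd.DataFrame(
        {
            "orthogroup_id": proteins,
            "ratio_parent1": medians[p1],
            "ratio_parent2": medians[p2],
            "ratio_hybrid": medians[hybrid_genotype],
            "ratio_mpv": ratio_mpv,
            "score": score,
        }
    )


def classify_solubility(
    score: np.ndarray | float,
    p_interaction: np.ndarray | float,
    score_threshold: float = 0.5,
    p_threshold: float = 0.05,
):
    """Threshold rule: significant interaction plus |score| >= threshold."""
    score = np.atleast_1d(np.asarray(score, float))
    p = np.atleast_1d(np.asarray(p_interaction, float))
    cls = np.full(score.shape, "no_shift", dtype=object)
    cls[(p <= p_threshold) & (score >= score_threshold)] = "more_soluble_parents"
    cls[(p <= p_threshold) & (score <= -score_threshold)] = "more_soluble_hybrid"
    return cls if cls.size > 1 else cls.item()


def analyze_solubility(
    matrices: dict[str, pd.DataFrame],
    design: pd.DataFrame,
    hybrid_genotype: str,
    parent_genotypes: tuple[str, str],
    score_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full per-protein solubility result: ratios, score, interaction p,
    and class, for one hybrid against its parents."""
    anova = interaction_anova(matrices, design, hybrid_genotype, parent_genotypes)
    ratios = solubility_score(matrices, design, hybrid_genotype, parent_genotypes)
    out = ratios.merge(anova, on="orthogroup_id", how="inner")
    out["hybrid"] = hybrid_genotype
    out["class"] = classify_solubility(
        out["score"].to_numpy(),
        out["p_interaction"].to_numpy(),
        score_threshold,
        p_threshold,
    )
    return out
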