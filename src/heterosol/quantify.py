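"""Peptide-to-protein quantification: feature filtering, median
normalization, left-censored imputation, and TOP3 summarization.

The feature table holds linear XIC peak areas for orthogroup-unique
peptides; missing observations are absent rows. Processing order follows
the standard label-free workflow: sparse features and single-peptide
proteins are removed, run intensities are median-aligned on the log2
scale, missing cells are imputed under a left-censoring model, and protein
abundance per run is the mean log2 intensity of the three most intense
peptides (TOP3).
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["peptide", "orthogroup_id", "subgenome_specific", "run_id", "intensity"]


def validate_features(features: pd.DataFrame) -> pd.DataFrame:
    missing = set(FEATURE_COLUMNS) - set(features.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    if (features["intensity"] <= 0).any():
        raise ValueError("intensities must be positive (linear XIC areas)")
    if features.duplicated(["peptide", "run_id"]).any():
        raise ValueError("duplicate (peptide, run_id) rows in feature table")
    return features


def filter_features(features: pd.DataFrame, min_runs: int = 3) -> pd.DataFrame:
    """Remove sparse peptides, then single-peptide proteins.

    Step 1 drops peptides observed in fewer than ``min_runs`` runs (the
    default keeps peptides seen 3+ times, i.e. removes one- and two-count
    peptides). Step 2 then drops proteins left with a single peptide. The
    order is fixed; the operation is idempotent.
    """
    validate_features(features)
    counts = features.groupby("peptide")["run_id"].transform("size")
    kept = features[counts >= min_runs]
    n_pep = kept.groupby("orthogroup_id")["peptide"].transform("nunique")
    kept = kept[n_pep >= 2]
    if kept.empty and not features.empty:
        warnings.warn("no features remain after filtering", stacklevel=2)
    return kept.reset_index(drop=True)


def median_normalize(
    features: pd.DataFrame, design: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Align every run's median log2 intensity to the global median of run
    medians (preserving the overall intensity scale); returns linear scale.
    """
    validate_features(features)
    if design is not None:
        empty = set(design["run_id"]) - set(features["run_id"])
        if empty:
            raise ValueError(
                f"run(s) with zero observed features: {sorted(empty)}"
            )
    log2i = np.log2(features["intensity"].to_numpy())
    run_median = pd.Series(log2i).groupby(features["run_id"].to_numpy()).median()
    target = run_median.median()
    shift = (target - run_median).reindex(features["run_id"]).to_numpy()
    out = features.copy()
    out["intensity"] = np.exp2(log2i + shift)
    return out


# ---------------------------------------------------------------------------
# censored imputation


def _censored_normal_fit(X, y_obs, obs_mask, bounds_cens, ridge=0.01):
    """MLE of a Gaussian accelerated-failure model on log2 intensity.

    Rows of X are cells (observed + censored); observed cells contribute
    density terms, censored cells contribute Phi((L - mu)/sigma) terms
    (the observation is known only to lie below its censoring bound L).
    A small ridge on the non-intercept coefficients keeps coefficients of
    levels appearing only in censored cells finite. Returns (beta, sigma,
    converged).
    """
    n, p = X.shape
    Xo, Xc = X[obs_mask], X[~obs_mask]
    yo = y_obs
    L = bounds_cens

    beta0 = np.zeros(p)
    beta0[0] = yo.mean() if yo.size else (L.mean() if L.size else 0.0)
    resid0 = yo - Xo @ beta0 if yo.size else np.array([1.0])
    sigma0 = max(float(np.std(resid0)), 0.05)
    theta0 = np.append(beta0, np.log(sigma0))

    pen = np.ones(p) * ridge
    pen[0] = 0.0

    def negloglik(theta):
        beta, logs = theta[:-1], theta[-1]
        sigma = np.exp(logs)
        nll = 0.0
        grad_beta = np.zeros(p)
        grad_logs = 0.0
        if yo.size:
            r = (yo - Xo @ beta) / sigma
            nll -= np.sum(norm.logpdf(r) - logs)
            grad_beta -= Xo.T @ r / sigma
            grad_logs -= np.sum(r * r - 1.0)
        if L.size:
            z = (L - Xc @ beta) / sigma
            logcdf = norm.logcdf(z)
            nll -= np.sum(logcdf)
            w = np.exp(norm.logpdf(z) - logcdf)  # inverse Mills ratio
            grad_beta += Xc.T @ w / sigma
            grad_logs += np.sum(w * z)
        nll += np.sum(pen * beta * beta)
        grad_beta += 2.0 * pen * beta
        return nll, np.append(grad_beta, grad_logs)

    res = minimize(negloglik, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    beta, sigma = res.x[:-1], float(np.exp(res.x[-1]))
    return beta, sigma, bool(res.success)


def impute_missing(
    features: pd.DataFrame,
    design: pd.DataFrame,
    method: str = "aft",
    genotype_subgenome: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Fill missing (peptide, run) cells under a left-censoring model.

    A cell is "missing" when the peptide was observed somewhere but not in
    that run; it is treated as censored at the run's minimum observed log2
    intensity. ``method='aft'`` fits, per protein, a Gaussian
    accelerated-failure regression on log2 intensity with peptide and run
    covariates and fills each censored cell with the model prediction
    truncated at the censoring bound; ``'bound'`` fills with the bound
    itself; ``'none'`` returns the input unchanged.

    ``genotype_subgenome`` maps pure-parent genotype names to their
    subgenome label so that structurally absent cells — a subgenome-specific
    peptide of the *other* parent in a pure-parent run — are not imputed.
    """
    if method == "none":
        return features
    if method not in ("aft", "bound"):
        raise ValueError(f"unknown imputation method {method!r}")
    validate_features(features)
    genotype_subgenome = genotype_subgenome or {}

    run_ids = design["run_id"].to_numpy()
    run_geno = dict(zip(design["run_id"], design["genotype"]))
    log2i = np.log2(features["intensity"].to_numpy())
    bound_of = (
        pd.Series(log2i).groupby(features["run_id"].to_numpy()).min().to_dict()
    )

    out_frames = [features]
    dropped = []
    for og, sub in features.groupby("orthogroup_id", sort=False):
        peptides = sub["peptide"].unique()
        pep_sub = dict(zip(sub["peptide"], sub["subgenome_specific"]))
        observed = set(zip(sub["peptide"], sub["run_id"]))
        cells = []
        for pep in peptides:
            spec = pep_sub[pep]
            for rid in run_ids:
                if rid not in bound_of:
                    continue  # run with no observations anywhere: no bound
                lab = genotype_subgenome.get(run_geno[rid])
                if lab is not None and spec in ("parent1", "parent2") and spec != lab:
                    continue  # structurally absent, not censored
                cells.append((pep, rid, (pep, rid) in observed))
        miss = [(p, r) for p, r, obs in cells if not obs]
        if not miss:
            continue
        if not any(obs for _, _, obs in cells):
            dropped.append(og)
            continue

        if method == "bound":
            fill = {(p, r): bound_of[r] for p, r in miss}
        else:
            pep_levels = {p: i for i, p in enumerate(peptides)}
            run_levels = {r: i for i, r in enumerate(run_ids)}
            npar = 1 + (len(pep_levels) - 1) + (len(run_levels) - 1)

            def row(pep, rid):
                x = np.zeros(npar)
                x[0] = 1.0
                pi = pep_levels[pep]
                if pi > 0:
                    x[pi] = 1.0
                ri = run_levels[rid]
                if ri > 0:
                    x[len(pep_levels) - 1 + ri] = 1.0
                return x

            X = np.array([row(p, r) for p, r, _ in cells])
            obs_mask = np.array([obs for _, _, obs in cells])
            obs_lookup = dict(
                zip(
                    zip(sub["peptide"], sub["run_id"]),
                    np.log2(sub["intensity"].to_numpy()),
                )
            )
            y_obs = np.array(
                [obs_lookup[(p, r)] for p, r, obs in cells if obs]
            )
            L = np.array([bound_of[r] for p, r, obs in cells if not obs])
            beta, sigma, ok = _censored_normal_fit(X, y_obs, obs_mask, L)
            if ok:
                mu = X[~obs_mask] @ beta
                # prediction truncated at the bound: the conditional mean
                # E[y | y < L] of the fitted normal, always below L
                z = (L - mu) / sigma
                mills = np.exp(norm.logpdf(z) - norm.logcdf(z))
                pred = mu - sigma * mills
                fill = {
                    (p, r): min(float(m), bound_of[r])
                    for (p, r), m in zip(miss, pred)
                }
            else:
                logger.warning("AFT fit did not converge for %s; using bound", og)
                fill = {(p, r): bound_of[r] for p, r in miss}

        add = pd.DataFrame(
            {
                "peptide": [p for p, r in miss],
                "orthogroup_id": og,
                "subgenome_specific": [pep_sub[p] for p, r in miss],
                "run_id": [r for p, r in miss],
                "intensity": np.exp2([fill[(p, r)] for p, r in miss]),
            }
        )
        out_frames.append(add)
    for og in dropped:
        warnings.warn(f"protein {og} has no observed cells; dropped", stacklevel=2)
    out = pd.concat(out_frames, ignore_index=True)
    out = out[~out["orthogroup_id"].isin(dropped)]
    return out.sort_values(["run_id", "peptide"], kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# TOP3


def top3_quantify(
    features: pd.DataFrame, design: pd.DataFrame, top_n: int = 3
) -> dict[str, pd.DataFrame]:
    """Protein abundance per run = mean log2 intensity of the ``top_n``
    most intense peptides in that run (all of them when fewer remain).

    Returns one protein x run matrix per fraction. Ties in intensity are
    broken by lexicographic peptide order so output is deterministic.
    """
    validate_features(features)
    unknown = set(features["run_id"]) - set(design["run_id"])
    if unknown:
        raise ValueError(f"runs absent from design: {sorted(unknown)}")

    f = features.sort_values(
        ["orthogroup_id", "run_id", "intensity", "peptide"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    top = f.groupby(["orthogroup_id", "run_id"], sort=False).head(top_n)
    ab = (
        np.log2(top["intensity"])
        .groupby([top["orthogroup_id"], top["run_id"]])
        .mean()
        .unstack("run_id")
    )

    frac_of = dict(zip(design["run_id"], design["fraction"]))
    matrices: dict[str, pd.DataFrame] = {}
    for fraction in dict.fromkeys(design["fraction"]):
        runs = [r for r in design["run_id"] if frac_of[r] == fraction]
        cols = [r for r in runs if r in ab.columns]
        if cols:
            matrices[fraction] = ab[cols]
    return matrices
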