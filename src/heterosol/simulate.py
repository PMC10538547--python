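"""Synthetic proteomes and label-free intensity tables with known truth.

The generator emulates the data underlying a hybrid/allopolyploid proteomics
study: two divergent parental proteomes sharing orthogroups, a sample design
of genotypes x fractions x replicates, and a peptide-level XIC intensity
table with injected nonadditive-expression, solubility-shift, and
subgenome-bias effects plus intensity-dependent (left-censored) missingness.
Every downstream stage can therefore be scored against ground truth.

Model, per run ``r`` and peptide ``j`` of orthogroup ``i`` (log2 scale)::

    y_ijr = baseline_i + genotype_effect + fraction_split + bias_term
            + offset_j + run_effect_r + Normal(0, residual_sd)

* parents sit at ``baseline_i``; the hybrid sits at the mid-parent value
  plus ``true_delta`` for nonadditive orthogroups;
* a soluble share ``s`` splits abundance between fractions: the soluble run
  adds ``log2(s)`` and the insoluble run ``log2(1-s)``; the whole-cell run
  is the linear sum of both (adds 0); ``s`` is shifted in the hybrid for
  solubility-shift orthogroups;
* in hybrid runs of a biased orthogroup, subgenome-specific peptides of the
  favored subgenome are scaled by ``bias_share`` and those of the other
  subgenome by ``1 - bias_share``;
* an observation is dropped (missing) with probability
  ``logistic((censor_threshold - y) * censor_steepness)``.

Pure-parent runs only ever contain peptides present in that parent's
homoeolog (own-subgenome-specific plus shared peptides).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .orthoproteome import PeptideRecord

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

GENOTYPES = ("parent1", "parent2", "hybrid1", "hybrid2")
FRACTIONS = ("whole", "soluble", "insoluble")


@dataclass
class SimulationParams:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated design: 3 biological replicates of 4
    genotypes (two parents, two reciprocal hybrids sharing truth) in 3
    fractions (whole / soluble / insoluble). Intensity units are log2 XIC
    area. The censoring threshold sits ~1 log2 unit below the typical
    fraction-level peptide intensity so that low-dose homoeolog peptides
    are preferentially lost, as in real data-dependent acquisition.
    """

    n_orthogroups: int = 100
    members_per_orthogroup: int = 1
    protein_length_range: tuple[int, int] = (150, 400)
    aa_divergence: float = 0.05
    n_replicates: int = 3
    baseline_log2_mean: float = 22.0
    baseline_log2_sd: float = 0.5
    peptide_offset_sd: float = 0.5
    run_effect_sd: float = 0.2
    residual_sd: float = 0.3
    frac_nonadditive: float = 0.15
    nonadditive_delta: float = 1.0
    frac_solubility_shift: float = 0.15
    solubility_share_parent: float = 0.5
    solubility_share_hybrid_shifted: float = 0.73
    frac_biased: float = 0.15
    bias_share: float = 0.9
    censor_threshold: float = 19.0
    censor_steepness: float = 3.0
    seed: int = 0
    genotypes: tuple[str, ...] = GENOTYPES
    fractions: tuple[str, ...] = FRACTIONS

    def validate(self) -> None:
        for name in (
            "frac_nonadditive",
            "frac_solubility_shift",
            "frac_biased",
            "aa_divergence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "solubility_share_parent",
            "solubility_share_hybrid_shifted",
            "bias_share",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_replicates < 2:
            raise ValueError(f"n_replicates must be >= 2, got {self.n_replicates}")
        if self.n_orthogroups < 1:
            raise ValueError("n_orthogroups must be >= 1")
        if self.members_per_orthogroup < 1:
            raise ValueError("members_per_orthogroup must be >= 1")
        lo, hi = self.protein_length_range
        if not (2 <= lo <= hi):
            raise ValueError(f"invalid protein_length_range {self.protein_length_range}")
        for name in (
            "baseline_log2_sd",
            "peptide_offset_sd",
            "run_effect_sd",
            "residual_sd",
            "censor_steepness",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        kwargs = dict(d)
        for key in ("protein_length_range", "genotypes", "fractions"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


NONADDITIVE_CLASSES = ("up", "down", "none")
SOLUBILITY_CLASSES = ("more_soluble_hybrid", "more_soluble_parent", "none")
BIAS_CLASSES = ("parent1", "parent2", "none")


def _og_id(i: int) -> str:
    return f"OG{i:05d}"


def generate_proteomes(params: SimulationParams):
    """Draw parental proteomes, the orthogroup catalog, and the truth table.

    Returns ``(sequences, catalog, truth)`` where ``sequences`` maps
    ``protein_id -> residue string``. Each orthogroup holds one homoeolog
    per parent (times ``members_per_orthogroup``); the parent2 homoeolog is
    derived from the parent1 sequence by independent substitutions at rate
    ``aa_divergence`` at non-initial positions (all proteins start with M,
    which also keeps the triple-lysine insulation airtight: no member can
    begin with proline).
    """
    from .orthoproteome import OrthogroupCatalog  # local to avoid cycle noise

    params.validate()
    rng = np.random.default_rng([params.seed, 1])
    lo, hi = params.protein_length_range

    sequences: dict[str, str] = {}
    entries = []
    for i in range(params.n_orthogroups):
        og = _og_id(i)
        for m in range(params.members_per_orthogroup):
            length = int(rng.integers(lo, hi + 1))
            body = rng.choice(AMINO_ACIDS, size=length - 1)
            p1 = "M" + "".join(body)
            sub = rng.random(length - 1) < params.aa_divergence
            body2 = body.copy()
            if sub.any():
                # substitute to a uniformly chosen *different* residue
                idx = np.flatnonzero(sub)
                cur = body2[idx]
                repl = rng.choice(AMINO_ACIDS, size=idx.size)
                clash = repl == cur
                while clash.any():
                    repl[clash] = rng.choice(AMINO_ACIDS, size=int(clash.sum()))
                    clash = repl == cur
                body2[idx] = repl
            p2 = "M" + "".join(body2)
            suffix = f"_{m}" if params.members_per_orthogroup > 1 else ""
            id1, id2 = f"{og}{suffix}_p1", f"{og}{suffix}_p2"
            sequences[id1] = p1
            sequences[id2] = p2
            entries.append((og, id1, "parent1"))
            entries.append((og, id2, "parent2"))
    catalog = OrthogroupCatalog(entries)

    truth_rng = np.random.default_rng([params.seed, 2])
    n = params.n_orthogroups
    nonadd = truth_rng.random(n) < params.frac_nonadditive
    nonadd_dir = np.where(truth_rng.random(n) < 0.5, "up", "down")
    sol = truth_rng.random(n) < params.frac_solubility_shift
    sol_dir = np.where(
        truth_rng.random(n) < 0.5, "more_soluble_hybrid", "more_soluble_parent"
    )
    biased = truth_rng.random(n) < params.frac_biased
    bias_dir = np.where(truth_rng.random(n) < 0.5, "parent1", "parent2")

    truth = pd.DataFrame(
        {
            "orthogroup_id": [_og_id(i) for i in range(n)],
            "true_nonadditive": np.where(nonadd, nonadd_dir, "none"),
            "true_delta": np.where(
                nonadd,
                np.where(nonadd_dir == "up", 1.0, -1.0) * params.nonadditive_delta,
                0.0,
            ),
            "true_solubility_class": np.where(sol, sol_dir, "none"),
            "true_bias": np.where(biased, bias_dir, "none"),
        }
    )
    return sequences, catalog, truth


def make_design(params: SimulationParams) -> pd.DataFrame:
    """Sample design: one LC-MS run per genotype x fraction x replicate."""
    rows = [
        {
            "run_id": f"{g}_{f}_r{r}",
            "genotype": g,
            "fraction": f,
            "replicate": r,
        }
        for g in params.genotypes
        for f in params.fractions
        for r in range(1, params.n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def simulate_intensities(
    params: SimulationParams,
    catalog,
    truth: pd.DataFrame,
    records: Sequence[PeptideRecord],
):
    """Simulate the peptide x run intensity table.

    ``records`` must come from digesting the generated proteomes and
    assigning the peptides back (``orthoproteome.digest`` +
    ``assign_peptides``); only peptides unique to one orthogroup are
    quantifiable and simulated. Returns ``(design, features)`` where
    ``features`` has columns peptide / orthogroup_id / subgenome_specific /
    run_id / intensity (linear XIC area; missing observations are absent
    rows).
    """
    params.validate()
    catalog_ogs = set(catalog.entries["orthogroup_id"])
    usable = [
        r
        for r in records
        if r.unique_to_orthogroup
        and r.within_member  # collapse artifacts have no physical peptide
        and r.subgenome_specific in ("parent1", "parent2", "shared")
    ]
    if not usable:
        raise ValueError("no quantifiable (orthogroup-unique) peptides supplied")
    og_of = {}
    for r in usable:
        og = r.hits[0][0]
        if og not in catalog_ogs:
            raise ValueError(f"peptide {r.sequence!r} hits unknown orthogroup {og}")
        og_of[r.sequence] = og

    truth = truth.set_index("orthogroup_id")
    missing_truth = set(og_of.values()) - set(truth.index)
    if missing_truth:
        raise ValueError(f"truth table lacks orthogroups: {sorted(missing_truth)[:3]}")

    design = make_design(params)
    rng = np.random.default_rng([params.seed, 3])

    peptides = np.array([r.sequence for r in usable])
    pep_og = np.array([og_of[p] for p in peptides])
    pep_sub = np.array([r.subgenome_specific for r in usable])

    ogs = truth.index.to_numpy()
    og_index = {og: i for i, og in enumerate(ogs)}
    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, len(ogs))
    delta = truth["true_delta"].to_numpy(float)
    sol_class = truth["true_solubility_class"].to_numpy()
    bias = truth["true_bias"].to_numpy()

    # soluble share per orthogroup x genotype-kind (parent vs hybrid)
    s_parent = np.full(len(ogs), params.solubility_share_parent)
    s_hybrid = np.where(
        sol_class == "more_soluble_hybrid",
        params.solubility_share_hybrid_shifted,
        np.where(
            sol_class == "more_soluble_parent",
            1.0 - params.solubility_share_hybrid_shifted,
            params.solubility_share_parent,
        ),
    )

    offsets = rng.normal(0.0, params.peptide_offset_sd, len(peptides))
    run_effects = rng.normal(0.0, params.run_effect_sd, len(design))

    oi = np.array([og_index[o] for o in pep_og])
    hybrid_genos = {g for g in params.genotypes if g.startswith("hybrid")}

    rows_pep, rows_run, rows_val = [], [], []
    for r_idx, run in design.iterrows():
        g, frac = run["genotype"], run["fraction"]
        is_hybrid = g in hybrid_genos
        if is_hybrid:
            observable = np.ones(len(peptides), bool)
        else:
            own = "parent1" if g == "parent1" else "parent2"
            observable = (pep_sub == own) | (pep_sub == "shared")
        if not observable.any():
            continue
        o = np.flatnonzero(observable)
        mu = baseline[oi[o]] + offsets[o] + run_effects[r_idx]
        if is_hybrid:
            mu = mu + delta[oi[o]]
            s = s_hybrid[oi[o]]
            fav = bias[oi[o]]
            scale = np.zeros(o.size)
            has_bias = fav != "none"
            fav_pep = has_bias & (pep_sub[o] == fav)
            dis_pep = has_bias & np.isin(pep_sub[o], ("parent1", "parent2")) & ~fav_pep
            scale[fav_pep] = np.log2(params.bias_share)
            scale[dis_pep] = np.log2(1.0 - params.bias_share)
            mu = mu + scale
        else:
            s = s_parent[oi[o]]
        if frac == "soluble":
            mu = mu + np.log2(s)
        elif frac == "insoluble":
            mu = mu + np.log2(1.0 - s)
        # whole = linear sum of soluble+insoluble means: adds log2(s+(1-s)) = 0
        y = mu + rng.normal(0.0, params.residual_sd, o.size)
        p_miss = expit((params.censor_threshold - y) * params.censor_steepness)
        keep = rng.random(o.size) >= p_miss
        rows_pep.append(o[keep])
        rows_run.append(np.full(int(keep.sum()), r_idx))
        rows_val.append(y[keep])

    o_all = np.concatenate(rows_pep)
    r_all = np.concatenate(rows_run)
    y_all = np.concatenate(rows_val)
    features = pd.DataFrame(
        {
            "peptide": peptides[o_all],
            "orthogroup_id": pep_og[o_all],
            "subgenome_specific": pep_sub[o_all],
            "run_id": design["run_id"].to_numpy()[r_all],
            "intensity": np.exp2(y_all),
        }
    )
    features = features.sort_values(["run_id", "peptide"], kind="mergesort").reset_index(
        drop=True
    )
    return design, features


def simulate_dataset(params: SimulationParams, digest_kwargs: dict | None = None):
    """Full generation path: proteomes -> collapse -> digest -> assign ->
    intensities. Returns a dict with every intermediate product.
    """
    from .orthoproteome import assign_peptides, build_collapsed_proteome, digest

    sequences, catalog, truth = generate_proteomes(params)
    proteome = build_collapsed_proteome(catalog, sequences)
    kw = digest_kwargs or {}
    peptides = sorted(
        {
            p.sequence
            for entry in proteome.values()
            for p in digest(entry.sequence, **kw)
        }
    )
    records = assign_peptides(peptides, proteome, catalog)
    design, features = simulate_intensities(params, catalog, truth, records)
    return {
        "params": params,
        "sequences": sequences,
        "catalog": catalog,
        "truth": truth,
        "proteome": proteome,
        "records": records,
        "design": design,
        "features": features,
    }


# ---------------------------------------------------------------------------
# abundance-level panel for statistical calibration


def simulate_abundance_panel(
    n_proteins: int,
    delta: float = 0.0,
    n_replicates: int = 3,
    residual_sd: float = 0.3,
    baseline_mean: float = 22.0,
    baseline_sd: float = 0.5,
    soluble_share_parent: float | None = None,
    soluble_share_hybrid: float | None = None,
    genotypes: tuple[str, str, str] = ("parent1", "parent2", "hybrid1"),
    seed: int = 0,
):
    """Protein-level abundance matrices with known effects, for calibration
    studies of the downstream tests (type-I error, effect recovery,
    solubility recovery) at sizes where sequence-level simulation would add
    nothing but runtime.

    Without soluble shares, returns ``(matrix, design)`` for a single
    fraction: hybrid deviates from the mid-parent value by ``delta`` (scalar
    or per-protein array). With shares, returns ``({"soluble": m1,
    "insoluble": m2}, design)`` where the fraction split follows the same
    ``log2(s)`` / ``log2(1-s)`` convention as the full generator.
    """
    p1, p2, hyb = genotypes
    rng = np.random.default_rng([seed, 11])
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    base = rng.normal(baseline_mean, baseline_sd, n_proteins)
    delta = np.broadcast_to(np.asarray(delta, float), (n_proteins,))

    def runs(fraction):
        return [
            {"run_id": f"{g}_{fraction}_r{r}", "genotype": g,
             "fraction": fraction, "replicate": r}
            for g in genotypes
            for r in range(1, n_replicates + 1)
        ]

    def matrix(fraction, share_of):
        rows = runs(fraction)
        data = np.empty((n_proteins, len(rows)))
        for j, run in enumerate(rows):
            mu = base.copy()
            if run["genotype"] == hyb:
                mu = mu + delta
            s = share_of(run["genotype"])
            if s is not None:
                if fraction == "soluble":
                    mu = mu + np.log2(s)
                else:
                    mu = mu + np.log2(1.0 - s)
            data[:, j] = mu + rng.normal(0.0, residual_sd, n_proteins)
        return pd.DataFrame(data, index=proteins,
                            columns=[r["run_id"] for r in rows]), rows

    if soluble_share_parent is None:
        m, rows = matrix("soluble", lambda g: None)
        return m, pd.DataFrame(rows)

    share_hyb = soluble_share_hybrid
    if share_hyb is None:
        share_hyb = soluble_share_parent
    share_hyb = np.broadcast_to(np.asarray(share_hyb, float), (n_proteins,))

    def share_of(g):
        return share_hyb if g == hyb else np.full(n_proteins, soluble_share_parent)

    sol, rows_s = matrix("soluble", share_of)
    insol, rows_i = matrix("insoluble", share_of)
    design = pd.DataFrame(rows_s + rows_i)
    return {"soluble": sol, "insoluble": insol}, design
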