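"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by the most transparent route available
(exhaustive enumeration, naive scanning, textbook formulas, or a reference
statistics library) so the implementation under test is checked against
logic it does not share.
"""

from __future__ import annotations

import numpy as np


def tryptic_sites(seq: str, proline_rule: bool = True) -> list[int]:
    """Cut positions (between seq[i-1] and seq[i]) by direct inspection."""
    return [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and not (proline_rule and seq[i + 1] == "P")
    ]


def brute_force_digest(
    seq: str,
    max_missed: int = 2,
    min_len: int = 1,
    max_len: int = 10**9,
    proline_rule: bool = True,
) -> set[tuple[str, int, int]]:
    """Enumerate every substring; keep the fully tryptic ones.

    A substring [i, j) is fully tryptic when i is 0 or a cut position and j
    is len(seq) or a cut position; its missed cleavages are the cut
    positions strictly inside (i, j).
    """
    cuts = set(tryptic_sites(seq, proline_rule))
    starts = {0} | cuts
    ends = {len(seq)} | cuts
    out = set()
    for i in range(len(seq)):
        for j in range(i + 1, len(seq) + 1):
            if i not in starts or j not in ends:
                continue
            if not (min_len <= j - i <= max_len):
                continue
            missed = sum(1 for c in cuts if i < c < j)
            if missed <= max_missed:
                out.add((seq[i:j], i, missed))
    return out


def naive_assignment(peptide: str, proteome, catalog) -> dict:
    """Scan every collapsed sequence character by character for the peptide
    and derive the flags from first principles."""
    label_of = dict(
        zip(catalog.entries["protein_id"], catalog.entries["parent_label"])
    )
    hits = []
    within = False
    for og, entry in proteome.items():
        seq = entry.sequence
        for pos in range(len(seq) - len(peptide) + 1):
            if seq[pos : pos + len(peptide)] != peptide:
                continue
            for b in entry.boundaries:
                if b.start < pos + len(peptide) and b.end > pos:
                    hits.append((og, b.protein_id, pos))
                    if b.start <= pos and pos + len(peptide) <= b.end:
                        within = True
    ogs = {h[0] for h in hits}
    labels = {label_of[h[1]] for h in hits}
    if not labels:
        sub = "none"
    elif labels == {"parent1"}:
        sub = "parent1"
    elif labels == {"parent2"}:
        sub = "parent2"
    elif labels <= {"parent1", "parent2"}:
        sub = "shared"
    else:
        sub = "none"
    return {
        "hits": sorted(hits),
        "unique_to_orthogroup": len(ogs) == 1,
        "subgenome_specific": sub,
        "within_member": within,
    }


def balanced_anova_interaction(y: np.ndarray, frac: np.ndarray, geno: np.ndarray):
    """Textbook cell-mean sums-of-squares F test for a balanced 2x2 design.

    y: observations; frac, geno: binary labels. Requires equal cell counts.
    Returns (F, p) for the interaction term.
    """
    from scipy.stats import f as f_dist

    cells = {}
    for fl in (0, 1):
        for gl in (0, 1):
            cells[(fl, gl)] = y[(frac == fl) & (geno == gl)]
    ns = {k: len(v) for k, v in cells.items()}
    n = ns[(0, 0)]
    assert all(v == n for v in ns.values()), "oracle requires balance"
    grand = y.mean()
    m_f = {fl: y[frac == fl].mean() for fl in (0, 1)}
    m_g = {gl: y[geno == gl].mean() for gl in (0, 1)}
    ss_int = n * sum(
        (cells[(fl, gl)].mean() - m_f[fl] - m_g[gl] + grand) ** 2
        for fl in (0, 1)
        for gl in (0, 1)
    )
    ss_err = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
    df_err = 4 * (n - 1)
    F = (ss_int / 1.0) / (ss_err / df_err)
    return F, float(f_dist.sf(F, 1, df_err))


def exhaustive_bias_call(n1: int, n2: int, threshold: float = 0.75) -> str:
    """Direct evaluation of the strict >3:1 rule for one count pair."""
    total = n1 + n2
    if total == 0:
        return "unbiased"
    frac = n1 / total
    if frac > threshold:
        return "parent1_biased"
    if frac < 1.0 - threshold:
        return "parent2_biased"
    return "unbiased"


def random_catalog(rng, n_orthogroups=3, members=(1, 3), length=(10, 60)):
    """Random Met-initial catalog + sequences for structural tests.

    Met-initial members mirror real proteins and keep the triple-lysine
    insulation airtight (a proline-initial member would defeat it).
    """
    from heterosol.orthoproteome import OrthogroupCatalog

    AA = list("ACDEFGHIKLMNPQRSTVWY")
    entries, sequences = [], {}
    for i in range(n_orthogroups):
        og = f"og{i}"
        n_mem = int(rng.integers(members[0], members[1] + 1))
        for m in range(n_mem):
            pid = f"{og}m{m}"
            L = int(rng.integers(length[0], length[1] + 1))
            sequences[pid] = "M" + "".join(rng.choice(AA, L - 1))
            entries.append((og, pid, "parent1" if m % 2 == 0 else "parent2"))
    return OrthogroupCatalog(entries), sequences
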