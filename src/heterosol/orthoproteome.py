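"""Orthogroup-collapsed proteome construction, tryptic digestion, and
peptide-to-orthogroup assignment.

Quantifying proteins in an allopolyploid against two parental proteomes
requires a search space in which homoeologous proteins do not compete for
peptides. The approach used here collapses each orthogroup into a single
entry by concatenating its member sequences with a ``KKK`` separator:
trypsin cleaves after every lysine, so the triple-lysine spacer insulates
members from each other and in-silico peptides (up to two missed cleavages)
never bridge two members. Peptides are then matched back to the collapsed
sequences by exact substring search and flagged for orthogroup uniqueness
and subgenome specificity.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SEPARATOR = "KKK"

PARENT_LABELS = ("parent1", "parent2")


# ---------------------------------------------------------------------------
# catalog


class OrthogroupCatalog:
    """Membership table mapping orthogroups to proteins.

    Each entry is ``(orthogroup_id, protein_id, parent_label)`` where
    ``parent_label`` is ``"parent1"``, ``"parent2"`` or ``"none"`` for
    proteins without a subgenome assignment. ``protein_id`` must be unique
    across the whole catalog; an orthogroup may contain members from one or
    both parents.
    """

    COLUMNS = ["orthogroup_id", "protein_id", "parent_label"]

    def __init__(self, entries: pd.DataFrame | Iterable[tuple]):
        if not isinstance(entries, pd.DataFrame):
            entries = pd.DataFrame(list(entries), columns=self.COLUMNS)
        df = entries.copy()
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        df = df[self.COLUMNS].astype(str)
        df["parent_label"] = df["parent_label"].replace({"nan": "none", "": "none"})
        if (df["orthogroup_id"] == "").any():
            raise ValueError("empty orthogroup_id in catalog")
        if df["protein_id"].duplicated().any():
            dup = df.loc[df["protein_id"].duplicated(), "protein_id"].iloc[0]
            raise ValueError(f"duplicate protein_id in catalog: {dup!r}")
        bad = ~df["parent_label"].isin([*PARENT_LABELS, "none"])
        if bad.any():
            raise ValueError(
                f"invalid parent_label: {df.loc[bad, 'parent_label'].iloc[0]!r}"
            )
        self.entries = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(dict.fromkeys(self.entries["orthogroup_id"]))

    def members(self, orthogroup_id: str) -> pd.DataFrame:
        return self.entries[self.entries["orthogroup_id"] == orthogroup_id]

    def parent_label(self, protein_id: str) -> str:
        row = self.entries[self.entries["protein_id"] == protein_id]
        if row.empty:
            raise KeyError(protein_id)
        return row["parent_label"].iloc[0]

    @classmethod
    def from_tsv(cls, path) -> "OrthogroupCatalog":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# collapsed proteome


@dataclass(frozen=True)
class MemberSpan:
    """Half-open span [start, end) of one member in a collapsed sequence."""

    protein_id: str
    start: int
    end: int


@dataclass
class CollapsedEntry:
    orthogroup_id: str
    sequence: str
    boundaries: list[MemberSpan]

    def member_sequences(self) -> dict[str, str]:
        """Recover the member sequences exactly from sequence + boundaries."""
        return {b.protein_id: self.sequence[b.start : b.end] for b in self.boundaries}


CollapsedProteome = dict[str, CollapsedEntry]


def build_collapsed_proteome(
    catalog: OrthogroupCatalog, sequences: Mapping[str, str]
) -> CollapsedProteome:
    """Concatenate each orthogroup's members with ``KKK`` separators.

    Members appear in catalog order; single-member orthogroups carry no
    separator. Raises ``KeyError`` for a catalog protein without a sequence
    and ``ValueError`` for an empty or non-alphabetic sequence.
    """
    proteome: CollapsedProteome = {}
    for og_id, group in catalog.entries.groupby("orthogroup_id", sort=False):
        parts: list[str] = []
        boundaries: list[MemberSpan] = []
        pos = 0
        for protein_id in group["protein_id"]:
            if protein_id not in sequences:
                raise KeyError(f"no sequence for protein {protein_id!r}")
            seq = sequences[protein_id]
            if not seq:
                raise ValueError(f"empty sequence for protein {protein_id!r}")
            if not seq.isalpha():
                raise ValueError(f"non-residue characters in {protein_id!r}")
            if parts:
                parts.append(SEPARATOR)
                pos += len(SEPARATOR)
            parts.append(seq)
            boundaries.append(MemberSpan(protein_id, pos, pos + len(seq)))
            pos += len(seq)
        proteome[og_id] = CollapsedEntry(og_id, "".join(parts), boundaries)
    return proteome


# ---------------------------------------------------------------------------
# digestion


@dataclass(frozen=True)
class DigestPeptide:
    sequence: str
    start: int
    missed_cleavages: int


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """Positions i such that trypsin cuts between sequence[i-1] and sequence[i].

    Cuts after K or R, suppressed when the next residue is P (standard
    trypsin convention) unless ``proline_rule`` is off. The returned list
    excludes 0 and len(sequence).
    """
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            sites.append(i + 1)
    return sites


def digest(
    sequence: str,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 50,
    proline_rule: bool = True,
) -> list[DigestPeptide]:
    """Fully-tryptic peptides of ``sequence`` with 0..max_missed missed
    cleavages, filtered to [min_len, max_len]. Positions are 0-based.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not sequence.isalpha():
        raise ValueError(f"non-residue characters in sequence: {sequence!r}")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    cuts = [0, *cleavage_sites(sequence, proline_rule), len(sequence)]
    peptides: list[DigestPeptide] = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 1 + max_missed + 1, len(cuts))):
            start, end = cuts[a], cuts[b]
            if min_len <= end - start <= max_len:
                peptides.append(
                    DigestPeptide(sequence[start:end], start, b - a - 1)
                )
    return peptides


def internal_missed_cleavages(peptide: str, proline_rule: bool = True) -> int:
    """Number of internal tryptic sites (missed cleavages) within a peptide."""
    return len(cleavage_sites(peptide, proline_rule))


# ---------------------------------------------------------------------------
# assignment


@dataclass
class PeptideRecord:
    """A peptide with all of its occurrences in the collapsed proteome.

    ``hits`` holds one ``(orthogroup_id, protein_id, position)`` triple per
    member whose span overlaps an occurrence; occurrences lying entirely
    within separator lysines contribute no hit. ``subgenome_specific`` is
    ``parent1``/``parent2`` when every hit member carries that one label,
    ``shared`` when both parents are represented, and ``none`` otherwise
    (no hits, or members without a subgenome label).
    """

    sequence: str
    missed_cleavages: int
    hits: list[tuple[str, str, int]] = field(default_factory=list)
    unique_to_orthogroup: bool = False
    subgenome_specific: str = "none"
    within_member: bool = False
    """True when at least one occurrence lies fully inside a member span.

    Peptides touching separator lysines in every occurrence are collapse
    artifacts with no physical counterpart in any parent protein."""


def _build_kmer_index(
    proteome: CollapsedProteome, k: int
) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for og_id, entry in proteome.items():
        seq = entry.sequence
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((og_id, i))
    return index


def assign_peptides(
    peptides: Iterable[str],
    proteome: CollapsedProteome,
    catalog: OrthogroupCatalog,
    equate_il: bool = False,
) -> list[PeptideRecord]:
    """Locate every occurrence of each peptide in every collapsed sequence
    and derive uniqueness and subgenome-specificity flags.

    Matching is exact substring search (seeded by a k-mer index so large
    catalogs stay tractable). With ``equate_il`` the search treats I and L
    as indistinguishable, as they are by mass spectrometry.
    """
    peptides = list(dict.fromkeys(peptides))  # dedupe, keep order
    if not peptides:
        return []
    label_of = dict(
        zip(catalog.entries["protein_id"], catalog.entries["parent_label"])
    )

    def norm(s: str) -> str:
        return s.replace("I", "L") if equate_il else s

    search_proteome = {
        og: CollapsedEntry(og, norm(e.sequence), e.boundaries)
        for og, e in proteome.items()
    }
    k = min(6, min(len(p) for p in peptides))
    index = _build_kmer_index(search_proteome, k)
    # member span lookup per orthogroup, sorted by start
    starts = {
        og: [b.start for b in e.boundaries] for og, e in proteome.items()
    }

    records = []
    for pep in peptides:
        q = norm(pep)
        rec = PeptideRecord(pep, internal_missed_cleavages(pep))
        seen = set()
        for og_id, pos in index.get(q[:k], ()):
            entry = search_proteome[og_id]
            if entry.sequence[pos : pos + len(q)] != q or (og_id, pos) in seen:
                continue
            seen.add((og_id, pos))
            lo, hi = pos, pos + len(q)
            bounds = proteome[og_id].boundaries
            # members whose [start,end) overlaps [lo,hi)
            i = max(0, bisect_right(starts[og_id], lo) - 1)
            for b in bounds[i:]:
                if b.start >= hi:
                    break
                if b.end > lo:
                    rec.hits.append((og_id, b.protein_id, pos))
                    if b.start <= lo and hi <= b.end:
                        rec.within_member = True
        ogs = {h[0] for h in rec.hits}
        rec.unique_to_orthogroup = len(ogs) == 1
        labels = {label_of.get(h[1], "none") for h in rec.hits}
        if not labels:
            rec.subgenome_specific = "none"
        elif labels == {"parent1"}:
            rec.subgenome_specific = "parent1"
        elif labels == {"parent2"}:
            rec.subgenome_specific = "parent2"
        elif labels <= {"parent1", "parent2"}:
            rec.subgenome_specific = "shared"
        else:
            rec.subgenome_specific = "none"
        records.append(rec)
    return records


def records_to_frame(records: Sequence[PeptideRecord]) -> pd.DataFrame:
    """Flatten peptide records to one row per peptide (annotation view)."""
    rows = []
    for r in records:
        ogs = sorted({h[0] for h in r.hits})
        rows.append(
            {
                "peptide": r.sequence,
                "missed_cleavages": r.missed_cleavages,
                "n_hits": len(r.hits),
                "orthogroup_id": ogs[0] if len(ogs) == 1 else "",
                "unique_to_orthogroup": r.unique_to_orthogroup,
                "subgenome_specific": r.subgenome_specific,
                "within_member": r.within_member,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peptide",
            "missed_cleavages",
            "n_hits",
            "orthogroup_id",
            "unique_to_orthogroup",
            "subgenome_specific",
            "within_member",
        ],
    )


def filter_cross_matches(
    records: Sequence[PeptideRecord],
    features: pd.DataFrame,
    design: pd.DataFrame,
    parent_genotypes: Mapping[str, str],
) -> tuple[set[str], set[str]]:
    """Discard orthogroups whose subgenome-specific peptides show up in the
    wrong pure parent.

    A parent1-specific peptide observed (non-missing intensity) in any run
    of the pure parent2 genotype — or vice versa — indicates the peptide
    matched the incorrect parental proteome; its orthogroup is discarded.
    Returns ``(kept, discarded)`` orthogroup-id sets over the universe of
    orthogroups hit by ``records``.

    ``parent_genotypes`` maps each pure-parent genotype name in the design
    to its subgenome label, e.g. ``{"parent1": "parent1", "parent2":
    "parent2"}``.
    """
    if not parent_genotypes:
        raise ValueError("parent_genotypes must name the pure parent genotypes")
    missing = set(parent_genotypes) - set(design["genotype"])
    if missing:
        raise ValueError(f"design lacks parent genotypes: {sorted(missing)}")

    run_genotype = dict(zip(design["run_id"], design["genotype"]))
    pep_ogs = {
        r.sequence: sorted({h[0] for h in r.hits}) for r in records
    }
    pep_spec = {
        r.sequence: r.subgenome_specific
        for r in records
        if r.subgenome_specific in PARENT_LABELS
    }
    universe = {og for ogs in pep_ogs.values() for og in ogs}

    spec = features["peptide"].map(pep_spec)
    expected = features["run_id"].map(run_genotype).map(parent_genotypes)
    wrong = features.loc[spec.notna() & expected.notna() & (spec != expected)]
    discarded: set[str] = set()
    for pep in wrong["peptide"].unique():
        discarded.update(pep_ogs.get(pep, ()))
    kept = universe - discarded
    if discarded:
        logger.info("cross-match filter discarded %d orthogroups", len(discarded))
    return kept, discarded
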