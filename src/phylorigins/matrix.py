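"""Supermatrix construction and diagnostics.

Covers the tabular half of a phylogenomic workflow downstream of orthology
inference: contamination screening of similarity-search hit tables (alien
index), pruning orthogroup gene trees to their largest single-copy subtree,
taxon-occupancy filtering, concatenation into a gap-filled supermatrix with
partition boundaries, occupancy/sparseness profiling (including binning
partitions by how many members of a focal clade they contain, the structure
behind contamination-vs-sparseness diagnostics), dataset overlap counts and
Fisher-exact term enrichment.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .phylo_io import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "HitTable",
    "read_hit_table",
    "alien_index_filter",
    "Partition",
    "prune_paralogs",
    "occupancy_filter",
    "Supermatrix",
    "concatenate_supermatrix",
    "OccupancyProfile",
    "occupancy_profile",
    "clade_filter",
    "overlap_report",
    "enrichment_test",
]

ALIEN_EPSILON = 1e-200  # pseudo e-value floor, the cited screening convention
MISSING_HIT_EVALUE = 1.0
GAP = "-"

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# ---------------------------------------------------------------------------
# Alien-index contamination screening
# ---------------------------------------------------------------------------


@dataclass
class HitTable:
    """Similarity-search hits with an ingroup/outgroup tag per subject.

    ``data`` columns: qseqid, sseqid, evalue, bitscore, group
    (group in {"ingroup", "outgroup"}).  Successive filtering rounds with
    different group taggings are expressed by building a new HitTable from
    the same raw hits with a different subject->group map.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"qseqid", "sseqid", "evalue", "group"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"hit table missing columns: {sorted(missing)}")
        if (self.data["evalue"] < 0).any():
            raise ValueError("e-values must be >= 0")
        bad = set(self.data["group"].unique()) - {"ingroup", "outgroup"}
        if bad:
            raise ValueError(f"unknown group tags: {sorted(bad)}")

    def queries(self) -> list[str]:
        return list(self.data["qseqid"].unique())


def read_hit_table(hits_path, group_map_path) -> HitTable:
    """Read BLAST outfmt-6 hits plus a two-column subject->group TSV."""
    hits = pd.read_csv(hits_path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    groups = pd.read_csv(
        group_map_path, sep="\t", header=None, names=["sseqid", "group"]
    )
    merged = hits.merge(groups, on="sseqid", how="left")
    untagged = merged["group"].isna()
    if untagged.any():
        n = int(untagged.sum())
        logger.warning("read_hit_table: dropping %d hits with untagged subjects", n)
        merged = merged[~untagged]
    logger.info("read_hit_table: %d hits for %d queries",
                len(merged), merged["qseqid"].nunique())
    return HitTable(merged[["qseqid", "sseqid", "evalue", "bitscore", "group"]])


def alien_index_filter(
    hits: HitTable,
    threshold: float = 0.0,
    all_queries=None,
):
    """Flag queries whose best outgroup hit beats their best ingroup hit.

    The per-query score is ``AI = ln(bestIngroupE + eps) - ln(bestOutgroupE
    + eps)`` with ``eps = 1e-200``; a missing side contributes E = 1.
    Queries are flagged when AI is *strictly* above the threshold (default
    0), i.e. the outgroup e-value is strictly better.  Queries listed in
    *all_queries* but absent from the table are kept with score 0 (logged).

    Returns ``(kept_ids, flagged_ids, scores)`` with scores a dict
    query -> AI.
    """
    best = (
        hits.data.groupby(["qseqid", "group"])["evalue"].min().unstack(fill_value=None)
    )
    scores: dict[str, float] = {}
    for q in best.index:
        e_in = best.at[q, "ingroup"] if "ingroup" in best.columns else math.nan
        e_out = best.at[q, "outgroup"] if "outgroup" in best.columns else math.nan
        e_in = MISSING_HIT_EVALUE if pd.isna(e_in) else float(e_in)
        e_out = MISSING_HIT_EVALUE if pd.isna(e_out) else float(e_out)
        scores[q] = math.log(e_in + ALIEN_EPSILON) - math.log(e_out + ALIEN_EPSILON)
    if all_queries is not None:
        orphans = [q for q in all_queries if q not in scores]
        if orphans:
            logger.info("alien_index_filter: %d queries with no hits kept (score 0)",
                        len(orphans))
        for q in orphans:
            scores[q] = 0.0
    flagged = sorted(q for q, s in scores.items() if s > threshold)
    kept = sorted(q for q in scores if scores[q] <= threshold)
    logger.info("alien_index_filter: %d kept, %d flagged", len(kept), len(flagged))
    return kept, flagged, scores


# ---------------------------------------------------------------------------
# Paralog pruning
# ---------------------------------------------------------------------------


def split_tip_label(label: str) -> tuple[str, str]:
    """Split an orthogroup tip label into (taxon, sequence id)."""
    taxon, sep, seqid = label.partition("|")
    if not sep or not taxon or not seqid:
        raise ValueError(f"tip label {label!r} is not of the form 'taxon|seqid'")
    return taxon, seqid


@dataclass
class Partition:
    """A single-copy locus: at most one sequence per taxon.

    ``alignment`` (taxon -> aligned sequence, equal lengths) is optional;
    ``n_study_taxa`` enables the ``occupancy`` property.
    """

    name: str
    members: dict = field(default_factory=dict)  # taxon -> seqid
    alignment: dict | None = None
    n_study_taxa: int | None = None

    def __post_init__(self):
        if self.alignment:
            lengths = {len(s) for s in self.alignment.values()}
            if len(lengths) > 1:
                raise ValueError(
                    f"unequal aligned lengths in partition {self.name!r}"
                )

    @property
    def taxa(self) -> list[str]:
        return sorted(self.members)

    @property
    def length(self) -> int:
        if not self.alignment:
            return 0
        return len(next(iter(self.alignment.values())))

    @property
    def occupancy(self) -> float:
        if not self.n_study_taxa:
            raise ValueError(f"partition {self.name!r} has no n_study_taxa set")
        return len(self.members) / self.n_study_taxa


def _collapse_low_support(tree: Phylogeny, threshold: float) -> Phylogeny:
    """Collapse internal nodes with support below *threshold* into polytomies."""
    if threshold <= 0:
        return tree
    new = tree.copy()
    for node in new.postorder():
        if node.is_leaf or node.parent is None:
            continue
        if node.support is not None and node.support < threshold:
            parent = node.parent
            idx = parent.children.index(node)
            for c in node.children:
                c.parent = parent
            parent.children[idx : idx + 1] = node.children
            node.children = []
            node.parent = None
    return Phylogeny(new.root, new.defaulted_lengths)


def prune_paralogs(
    og: Phylogeny, support_collapse: float = 0.0, name: str = "partition"
) -> Partition:
    """Largest single-copy taxon selection from an orthogroup gene tree.

    After collapsing internal nodes with support below *support_collapse*
    (default 0: no collapse), same-taxon sequences that form a
    tip-monophyletic group are merged into one representative (the
    longest-named sequence id, ties broken lexicographically).  Every node's
    induced clade — including the whole tree — is then a candidate, valid
    when it contains at most one sequence per taxon; the candidate with the
    most distinct taxa wins.  Ties prefer more underlying sequences, then
    the lexicographically smallest sorted tip-label list.  The worst case
    (every clade conflicted) returns a single tip.
    """
    tree = _collapse_low_support(og, support_collapse)

    # clade tip sets, postorder
    nodes = tree.postorder()
    tipsets: dict[int, list[str]] = {}
    for n in nodes:
        if n.is_leaf:
            tipsets[id(n)] = [n.label]
        else:
            tipsets[id(n)] = [t for c in n.children for t in tipsets[id(c)]]

    # merge tip-monophyletic same-taxon groups: map each maximal
    # single-taxon clade to one representative sequence
    merged_rep: dict[str, tuple[str, int]] = {}  # tip label -> (rep label, n seqs)
    consumed: set[str] = set()
    for n in nodes:
        labels = tipsets[id(n)]
        taxa = {split_tip_label(l)[0] for l in labels}
        if len(taxa) == 1 and len(labels) > 1:
            parent = n.parent
            if parent is not None:
                ptaxa = {split_tip_label(l)[0] for l in tipsets[id(parent)]}
                if len(ptaxa) == 1:
                    continue  # not maximal
            rep = max(labels, key=lambda l: (len(split_tip_label(l)[1]),
                                             split_tip_label(l)[1]))
            for l in labels:
                consumed.add(l)
                merged_rep[l] = (rep, len(labels))

    def effective(labels):
        """Collapse merged groups; (taxon -> rep seq label, n raw seqs)."""
        chosen: dict[str, str] = {}
        seen_reps: set[str] = set()
        nseqs = 0
        for l in labels:
            taxon = split_tip_label(l)[0]
            if l in merged_rep:
                rep, _k = merged_rep[l]
                if rep in seen_reps:
                    continue
                seen_reps.add(rep)
                nseqs += _k
                if taxon in chosen:
                    return None, 0
                chosen[taxon] = rep
            else:
                nseqs += 1
                if taxon in chosen:
                    return None, 0
                chosen[taxon] = l
        return chosen, nseqs

    best = None  # (ntaxa, nseqs, neg-sorted-labels, chosen)
    for n in nodes:
        chosen, nseqs = effective(tipsets[id(n)])
        if chosen is None:
            continue
        key = (len(chosen), nseqs, [s for s in sorted(chosen.values())])
        if best is None:
            better = True
        else:
            bkey = best[0]
            better = (key[0], key[1]) > (bkey[0], bkey[1]) or (
                (key[0], key[1]) == (bkey[0], bkey[1]) and key[2] < bkey[2]
            )
        if better:
            best = (key, chosen)

    chosen = best[1]
    members = {t: split_tip_label(l)[1] for t, l in chosen.items()}
    return Partition(name=name, members=members)


# ---------------------------------------------------------------------------
# Occupancy filtering, concatenation, profiling
# ---------------------------------------------------------------------------


def occupancy_filter(
    partitions: list[Partition],
    min_occupancy: float = 0.5,
    n_taxa: int | None = None,
) -> list[Partition]:
    """Retain partitions whose taxon occupancy strictly exceeds the cutoff.

    The inequality is strict ("exceeds"): occupancy exactly at the cutoff is
    dropped.  ``n_taxa`` overrides per-partition ``n_study_taxa``.
    """
    if not 0 <= min_occupancy < 1:
        raise ValueError("min_occupancy must be in [0, 1)")
    kept = []
    for p in partitions:
        total = n_taxa if n_taxa is not None else p.n_study_taxa
        if not total:
            raise ValueError(f"partition {p.name!r}: study taxon count unknown")
        if len(p.members) / total > min_occupancy:
            kept.append(p)
    logger.info("occupancy_filter: %d of %d partitions retained (> %.0f%%)",
                len(kept), len(partitions), 100 * min_occupancy)
    return kept


@dataclass
class Supermatrix:
    """Concatenated alignment with 1-based inclusive partition boundaries."""

    taxa: list
    rows: dict  # taxon -> concatenated sequence
    boundaries: list  # (partition name, start, end)

    def __post_init__(self):
        total = self.boundaries[-1][2] if self.boundaries else 0
        for t in self.taxa:
            if len(self.rows[t]) != total:
                raise ValueError(f"row length mismatch for taxon {t!r}")

    @property
    def length(self) -> int:
        return self.boundaries[-1][2] if self.boundaries else 0

    def split(self) -> list[Partition]:
        """Recover the per-partition alignments from the boundaries."""
        out = []
        for name, start, end in self.boundaries:
            aln = {}
            for t in self.taxa:
                seq = self.rows[t][start - 1 : end]
                if set(seq) != {GAP}:
                    aln[t] = seq
            out.append(
                Partition(
                    name=name,
                    members={t: t for t in aln},
                    alignment=aln,
                    n_study_taxa=len(self.taxa),
                )
            )
        return out

    def to_fasta(self) -> str:
        return "".join(f">{t}\n{self.rows[t]}\n" for t in self.taxa)

    def partition_file(self, datatype: str = "PROT") -> str:
        """RAxML-style partition definitions ("PROT, name = start-end")."""
        return "".join(
            f"{datatype}, {name} = {start}-{end}\n"
            for name, start, end in self.boundaries
        )


def concatenate_supermatrix(partitions: list[Partition], taxa: list[str]) -> Supermatrix:
    """Concatenate aligned partitions over a shared taxon list.

    Partitions are ordered deterministically by name; taxa missing from a
    partition are gap-filled.  Partitions must carry alignments of equal
    within-partition length.
    """
    if not partitions:
        raise ValueError("no partitions to concatenate")
    ordered = sorted(partitions, key=lambda p: p.name)
    rows = {t: [] for t in taxa}
    boundaries = []
    pos = 0
    for p in ordered:
        if not p.alignment:
            raise ValueError(f"partition {p.name!r} has no alignment")
        length = p.length
        for t in taxa:
            seq = p.alignment.get(t)
            if seq is not None and len(seq) != length:
                raise ValueError(f"unequal sequence lengths in partition {p.name!r}")
            rows[t].append(seq if seq is not None else GAP * length)
        boundaries.append((p.name, pos + 1, pos + length))
        pos += length
    return Supermatrix(
        taxa=list(taxa),
        rows={t: "".join(parts) for t, parts in rows.items()},
        boundaries=boundaries,
    )


@dataclass
class OccupancyProfile:
    """Occupancy diagnostics for a set of partitions.

    ``clade_histograms[clade][m]`` counts partitions containing exactly
    ``m`` members of the named clade.
    """

    taxon_counts: pd.Series  # partitions per taxon
    partition_counts: pd.Series  # taxa per partition
    clade_histograms: dict


def occupancy_profile(
    partitions: list[Partition],
    taxa: list[str],
    clades: dict | None = None,
) -> OccupancyProfile:
    """Per-taxon and per-partition data counts plus per-clade histograms."""
    clades = clades or {}
    taxa_set = set(taxa)
    for cname, members in clades.items():
        unknown = set(members) - taxa_set
        if unknown:
            raise ValueError(f"clade {cname!r} has unknown members: {sorted(unknown)}")
    taxon_counts = pd.Series(0, index=list(taxa), dtype=int)
    partition_counts = {}
    histograms = {cname: {} for cname in clades}
    for p in partitions:
        present = [t for t in p.members if t in taxa_set]
        partition_counts[p.name] = len(present)
        for t in present:
            taxon_counts[t] += 1
        for cname, members in clades.items():
            m = len(set(members) & set(present))
            histograms[cname][m] = histograms[cname].get(m, 0) + 1
    return OccupancyProfile(
        taxon_counts=taxon_counts,
        partition_counts=pd.Series(partition_counts, dtype=int),
        clade_histograms=histograms,
    )


def clade_filter(
    partitions: list[Partition],
    clade,
    min_members: int = 3,
    drop_absent: bool = False,
) -> list[Partition]:
    """Retain partitions with at least ``min_members`` clade taxa present.

    Partitions containing *no* clade member at all are retained unchanged by
    default (they carry no contamination risk from that clade); pass
    ``drop_absent=True`` to drop them too.
    """
    if min_members < 0:
        raise ValueError("min_members must be >= 0")
    clade = set(clade)
    kept = []
    for p in partitions:
        m = len(clade & set(p.members))
        if m == 0 and not drop_absent:
            kept.append(p)
        elif m >= min_members:
            kept.append(p)
    logger.info("clade_filter: %d of %d partitions retained", len(kept),
                len(partitions))
    return kept


# ---------------------------------------------------------------------------
# Dataset overlap and enrichment
# ---------------------------------------------------------------------------


def overlap_report(locus_maps: list[tuple[str, dict]]) -> dict:
    """Venn-style intersection counts of reference-locus complements.

    Each entry is ``(dataset name, partition -> reference locus id)``.
    Duplicate loci within one dataset are deduplicated with a warning.
    Returns ``{frozenset of dataset names: size of their intersection}`` for
    every non-empty subset, plus singleton set sizes.
    """
    sets: dict[str, set] = {}
    for name, mapping in locus_maps:
        loci = list(mapping.values())
        uniq = set(loci)
        if len(uniq) < len(loci):
            logger.warning("overlap_report: %d duplicate loci in %s deduplicated",
                           len(loci) - len(uniq), name)
        sets[name] = uniq
    names = list(sets)
    out: dict = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(sets[c] for c in combo))
            out[frozenset(combo)] = len(inter)
    return out


def enrichment_test(
    subset_counts: dict,
    background_counts: dict,
    subset_total: int | None = None,
    background_total: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term Fisher exact tests of a subset against its background.

    For each term the 2x2 table is (term / not-term) x (subset /
    background-minus-subset); two-sided exact p-values are
    Benjamini-Hochberg adjusted and calls made at q < *alpha* ("enriched"
    when the odds ratio exceeds 1, "depleted" below, otherwise "ns").  The
    subset must be contained in the background.
    """
    subset_total = subset_total if subset_total is not None else sum(subset_counts.values())
    background_total = (
        background_total if background_total is not None else sum(background_counts.values())
    )
    rows = []
    for term in sorted(set(subset_counts) | set(background_counts)):
        a = int(subset_counts.get(term, 0))
        bg = int(background_counts.get(term, 0))
        if a < 0 or bg < 0:
            raise ValueError("counts must be non-negative")
        if a > bg:
            raise ValueError(f"term {term!r}: subset count exceeds background")
        b = subset_total - a
        c = bg - a
        d = (background_total - bg) - b
        if b < 0 or d < 0:
            raise ValueError("totals inconsistent with counts")
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"term": term, "subset": a, "background": bg,
                     "odds_ratio": odds, "p_value": p})
    df = pd.DataFrame(rows)
    if df.empty:
        df["q_value"] = []
        df["call"] = []
        return df
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]

    def call(row):
        if row.q_value >= alpha:
            return "ns"
        return "enriched" if row.odds_ratio > 1 else "depleted"

    df["call"] = df.apply(call, axis=1)
    return df
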