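"""Synthetic data with the statistical structure the pipeline assumes.

Generates every input the other modules consume, with ground truth
attached, so the whole pipeline is testable without any downloads:

* Yule (pure-birth) ultrametric trees — the simplest adequate tree model
  for method testing (death rate 0);
* binary traits under three regimes: ``mk`` (forward simulation under known
  gain/loss rates, returning the generating history), ``single_origin``
  (one clade painted state 1: exactly one origin by construction) and
  ``scattered`` (iid Bernoulli tips, no tree signal);
* orthogroup gene trees with in-/out-paralogs, taxon dropout and
  clade-specific contaminant tips whose probability *decreases* (logistic
  in the member count) as more focal-clade taxa are present in the
  orthogroup — sparse focal representation is where contamination
  concentrates;
* hit tables in which clean sequences have better ingroup than outgroup
  e-values and contaminants the reverse.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from . import simmap
from .matrix import Partition
from .mk import MkModel
from .phylo_io import Node, Phylogeny, TraitMatrix, prune_taxa

__all__ = [
    "SimulationConfig",
    "Orthogroup",
    "simulate_tree",
    "simulate_traits",
    "simulate_orthogroups",
    "simulate_hit_table",
    "partition_alignments",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for every generator; defaults are the study-scale conditions.

    A ~60-tip ingroup, equal gain/loss rates of 0.47 (a typical empirically
    fitted magnitude for a binary ecological trait on a tree of this depth),
    a focal "sparse" clade of 5 taxa whose per-sequence contamination
    probability falls logistically with the number of clade members present
    in an orthogroup, and partition lengths of 50-300 aligned positions.
    """

    seed: int = 0
    n_tips: int = 60
    birth_rate: float = 1.0
    tree_depth: float | None = None
    gain_rate: float = 0.47
    loss_rate: float = 0.47
    root_policy: str = "flat"
    trait_regime: str = "mk"  # mk | single_origin | scattered
    scattered_p: float = 0.5
    clade_fraction_range: tuple = (0.1, 0.5)  # single_origin clade size bounds
    n_orthogroups: int = 200
    dropout_prob: float = 0.2
    focal_dropout_prob: float = 0.55
    paralog_prob: float = 0.08
    out_paralog_prob: float = 0.05
    contamination_base: float = 0.8
    contamination_mid: float = 2.0
    contamination_slope: float = 1.0
    focal_clade_size: int = 5
    partition_length_range: tuple = (50, 300)
    hit_flip_prob: float = 0.02

    def contamination_prob(self, n_focal_present: int) -> float:
        """Per-sequence contamination probability given focal-clade presence."""
        return float(
            self.contamination_base
            * expit(self.contamination_slope * (self.contamination_mid - n_focal_present))
        )

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _rng(config_or_seed):
    if isinstance(config_or_seed, np.random.Generator):
        return config_or_seed
    if isinstance(config_or_seed, SimulationConfig):
        return np.random.default_rng(config_or_seed.seed)
    return np.random.default_rng(config_or_seed)


def _taxon_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"t{str(i + 1).zfill(width)}" for i in range(n)]


def simulate_tree(config: SimulationConfig, rng=None) -> Phylogeny:
    """Ultrametric Yule tree with ``config.n_tips`` tips.

    Standard pure-birth construction: while k lineages exist the next split
    waits Exp(k * birth_rate); the final epoch (k = n) is included, so the
    expected root-to-tip depth is sum_{k=2..n} 1/(k * birth_rate).

    With ``config.tree_depth`` set, every branch is rescaled so the
    root-to-tip depth equals that value.  Empirical phylogenomic trees carry
    branch lengths in substitutions per site (depths of order 0.1-1), and
    trait-rate magnitudes are only interpretable relative to that scale;
    rescaling lets exaggerated gain:loss settings like 10:1 remain
    meaningful on a tree whose depth mimics such data.
    """
    if config.n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = _rng(rng if rng is not None else config)
    lam = config.birth_rate
    root = Node()
    active = []
    for _ in range(2):
        c = Node(length=0.0)
        root.add_child(c)
        active.append(c)
    for k in range(2, config.n_tips + 1):
        dt = rng.exponential(1.0 / (k * lam))
        for node in active:
            node.length += dt
        if k < config.n_tips:
            i = rng.integers(len(active))
            split = active[i]
            new = []
            for _ in range(2):
                c = Node(length=0.0)
                split.add_child(c)
                new.append(c)
            active[i] = new[0]
            active.append(new[1])
    names = _taxon_names(config.n_tips)
    # deterministic naming in left-to-right tip order for reproducible output
    tips = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.children:
            stack.extend(reversed(node.children))
        else:
            tips.append(node)
    for name, tip in zip(names, tips):
        tip.label = name
    if config.tree_depth is not None:
        depth = 0.0
        node = tips[0]
        while node.parent is not None:
            depth += node.length
            node = node.parent
        factor = config.tree_depth / depth
        stack = [root]
        while stack:
            node = stack.pop()
            if node.length is not None:
                node.length *= factor
            stack.extend(node.children)
    return Phylogeny(root)


def simulate_traits(
    tree: Phylogeny, config: SimulationConfig, rng=None
) -> tuple[TraitMatrix, simmap.MappedHistory | None]:
    """Tip states for one binary character plus the generating history.

    ``mk``: forward simulation under (gain_rate, loss_rate); the returned
    history is ground truth for origin counts.  ``single_origin``: a random
    internal clade (size within ``clade_fraction_range`` of the tips) is
    painted state 1; the history has exactly one gain, placed at the
    midpoint of the branch subtending the clade.  ``scattered``: iid
    Bernoulli(scattered_p) tips; no generating history exists (None).
    """
    rng = _rng(rng if rng is not None else config)
    regime = config.trait_regime
    if regime == "mk":
        model = MkModel(config.gain_rate, config.loss_rate,
                        root_policy=config.root_policy)
        hist = simmap.simulate_history_prior(tree, model, rng)
        flat = tree.postorder()
        states = {
            n.label: int(hist.node_states[i])
            for i, n in enumerate(flat)
            if n.is_leaf
        }
        return TraitMatrix.from_dict(states), hist

    if regime == "single_origin":
        nodes = tree.postorder()
        n = tree.n_tips
        lo = max(2, int(np.ceil(config.clade_fraction_range[0] * n)))
        hi = max(lo, int(np.floor(config.clade_fraction_range[1] * n)))
        candidates = [
            node
            for node in nodes
            if not node.is_leaf
            and node.parent is not None
            and lo <= len(node.clade_tips()) <= hi
        ]
        if not candidates:
            raise ValueError("no internal clade within the configured size range")
        chosen = candidates[rng.integers(len(candidates))]
        clade = {id(t) for t in chosen.clade_tips()}
        clade_nodes = set()
        stack = [chosen]
        while stack:
            x = stack.pop()
            clade_nodes.add(id(x))
            stack.extend(x.children)
        node_states = np.array(
            [1 if id(node) in clade_nodes else 0 for node in nodes], dtype=np.int8
        )
        segments = []
        index = {id(node): i for i, node in enumerate(nodes)}
        for node in nodes[:-1]:
            t = node.length or 0.0
            if id(node) == id(chosen):
                segments.append([(0, t / 2.0), (1, t / 2.0)])
            else:
                s = int(node_states[index[id(node)]])
                segments.append([(s, t)])
        segments.append([])
        hist = simmap.MappedHistory(tree=tree, node_states=node_states,
                                    segments=segments)
        states = {node.label: int(node_states[index[id(node)]])
                  for node in nodes if node.is_leaf}
        return TraitMatrix.from_dict(states), hist

    if regime == "scattered":
        states = {
            label: int(rng.random() < config.scattered_p)
            for label in tree.tip_labels
        }
        return TraitMatrix.from_dict(states), None

    raise ValueError(f"unknown trait regime: {regime!r}")


# ---------------------------------------------------------------------------
# Orthogroups, contamination, hit tables
# ---------------------------------------------------------------------------


@dataclass
class Orthogroup:
    """A simulated orthogroup gene tree with per-tip ground truth.

    ``labels`` maps each tip label ("taxon|seqid") to its true status in
    {"clean", "paralog", "contaminant"}; ``n_focal`` is the number of
    focal-clade taxa with at least one sequence present.
    """

    name: str
    tree: Phylogeny
    labels: dict
    n_focal: int
    focal_clade: list = field(default_factory=list)


def _default_clades(tree: Phylogeny, config: SimulationConfig):
    """Pick a focal 'sparse' clade: the internal clade whose size is closest
    to config.focal_clade_size."""
    best = None
    for node in tree.postorder():
        if node.is_leaf or node.parent is None:
            continue
        size = len(node.clade_tips())
        key = (abs(size - config.focal_clade_size), size)
        if best is None or key < best[0]:
            best = (key, node)
    clade = sorted(t.label for t in best[1].clade_tips())
    return {"sparse_clade": clade}


def simulate_orthogroups(
    config: SimulationConfig,
    tree: Phylogeny | None = None,
    clades: dict | None = None,
    rng=None,
) -> tuple[list[Orthogroup], pd.DataFrame]:
    """Orthogroup gene trees with planted paralogs and contaminants.

    Per orthogroup: taxa drop out independently (focal-clade taxa at the
    higher ``focal_dropout_prob``, making the focal clade sparse); the gene
    tree is the species tree pruned to the survivors; each tip duplicates
    in place (in-paralog) with ``paralog_prob``; one out-paralog is grafted
    onto a random branch with ``out_paralog_prob``; each focal-clade
    sequence is contaminant with probability
    ``contamination_prob(n_focal_present)``.  Returns the orthogroups and a
    tidy ground-truth table (orthogroup, tip, taxon, status, n_focal).
    """
    rng = _rng(rng if rng is not None else config)
    if tree is None:
        tree = simulate_tree(config, rng)
    if clades is None:
        clades = _default_clades(tree, config)
    focal_name = next(iter(clades))
    focal = set(clades[focal_name])
    taxa = tree.tip_labels

    ogs: list[Orthogroup] = []
    records = []
    for k in range(config.n_orthogroups):
        name = f"og{k:04d}"
        while True:
            present = [
                t
                for t in taxa
                if rng.random()
                >= (config.focal_dropout_prob if t in focal else config.dropout_prob)
            ]
            if len(present) >= 2:
                break
        gtree = prune_taxa(tree, set(taxa) - set(present))
        counter = {t: 0 for t in present}

        def _seqid(taxon):
            counter[taxon] += 1
            return f"{name}_s{counter[taxon]}"

        for tip in gtree.tips():
            tip.label = f"{tip.label}|{_seqid(tip.label)}"

        status: dict[str, str] = {}
        # in-paralogs: duplicate a tip in place (tip-monophyletic pair)
        for tip in list(gtree.tips()):
            taxon = tip.label.split("|", 1)[0]
            if rng.random() < config.paralog_prob:
                left = Node(label=tip.label, length=tip.length * 0.1)
                right = Node(label=f"{taxon}|{_seqid(taxon)}",
                             length=tip.length * 0.1)
                tip.children = []
                tip.add_child(left)
                tip.add_child(right)
                tip.label = None
                status[right.label] = "paralog"
        gtree = Phylogeny(gtree.root)
        # out-paralog: graft a stray copy of a random taxon onto a random branch
        if rng.random() < config.out_paralog_prob and len(gtree.tips()) >= 3:
            taxon = present[rng.integers(len(present))]
            nodes = [n for n in gtree.postorder() if n.parent is not None]
            attach = nodes[rng.integers(len(nodes))]
            parent = attach.parent
            idx = parent.children.index(attach)
            mid = Node(length=(attach.length or 0.0) / 2.0)
            stray = Node(label=f"{taxon}|{_seqid(taxon)}", length=0.05)
            attach.length = (attach.length or 0.0) / 2.0
            parent.children[idx] = mid
            mid.parent = parent
            mid.add_child(attach)
            mid.add_child(stray)
            status[stray.label] = "paralog"
        gtree = Phylogeny(gtree.root)

        n_focal = len(focal & set(present))
        p_cont = config.contamination_prob(n_focal) if n_focal else 0.0
        for tip in gtree.tips():
            taxon = tip.label.split("|", 1)[0]
            if tip.label in status:
                continue
            if taxon in focal and rng.random() < p_cont:
                status[tip.label] = "contaminant"
            else:
                status[tip.label] = "clean"
        og = Orthogroup(name=name, tree=gtree, labels=status, n_focal=n_focal,
                        focal_clade=sorted(focal))
        ogs.append(og)
        for tip_label, st in status.items():
            records.append(
                {
                    "orthogroup": name,
                    "tip": tip_label,
                    "taxon": tip_label.split("|", 1)[0],
                    "status": st,
                    "n_focal": n_focal,
                }
            )
    truth = pd.DataFrame(records)
    return ogs, truth


def simulate_hit_table(
    orthogroups: list[Orthogroup],
    config: SimulationConfig,
    rng=None,
):
    """Hit table mirroring what contamination looks like in similarity space.

    Clean sequences draw a best-ingroup e-value far below (better than)
    their best-outgroup e-value; contaminants the reverse; a small
    ``hit_flip_prob`` swaps the two to emulate borderline cases.  E-values
    are log-uniform in [1e-180, 1].  Returns ``(HitTable-ready DataFrame,
    subject -> group map)``.
    """
    rng = _rng(rng if rng is not None else config)
    rows = []
    for og in orthogroups:
        for tip_label, status in og.labels.items():
            qseqid = f"{og.name}|{tip_label}"
            good = 10.0 ** rng.uniform(-180.0, -30.0)
            bad = 10.0 ** rng.uniform(-20.0, 0.0)
            contaminated = status == "contaminant"
            if rng.random() < config.hit_flip_prob:
                contaminated = not contaminated
            e_in, e_out = (bad, good) if contaminated else (good, bad)
            rows.append(
                {
                    "qseqid": qseqid,
                    "sseqid": "ingroup_ref",
                    "evalue": e_in,
                    "bitscore": max(25.0, -10.0 * np.log10(e_in + 1e-300)),
                    "group": "ingroup",
                }
            )
            rows.append(
                {
                    "qseqid": qseqid,
                    "sseqid": "outgroup_ref",
                    "evalue": e_out,
                    "bitscore": max(25.0, -10.0 * np.log10(e_out + 1e-300)),
                    "group": "outgroup",
                }
            )
    df = pd.DataFrame(rows)
    group_map = {"ingroup_ref": "ingroup", "outgroup_ref": "outgroup"}
    return df, group_map


def partition_alignments(
    partitions: list[Partition],
    config: SimulationConfig,
    rng=None,
) -> list[Partition]:
    """Attach placeholder aligned sequences of random length to partitions.

    Residues are drawn uniformly from the 20 amino acids; no residue-level
    evolution is simulated (the matrix stages only need shapes and
    presence/absence structure).
    """
    rng = _rng(rng if rng is not None else config)
    lo, hi = config.partition_length_range
    out = []
    for p in partitions:
        length = int(rng.integers(lo, hi + 1))
        aln = {
            taxon: "".join(
                AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length)
            )
            for taxon in sorted(p.members)
        }
        out.append(
            Partition(
                name=p.name,
                members=dict(p.members),
                alignment=aln,
                n_study_taxa=p.n_study_taxa,
            )
        )
    return out
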