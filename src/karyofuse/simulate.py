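"""Synthetic data with controlled ground truth for the comparative pipeline.

Generates ultrametric birth-death trees, evolves karyotype states along them
under a known rate model, assigns genus-structured binomial labels, and
withholds or scrambles a configurable fraction of the trait table so that
the genus-level matching step has real work to do.  Every run emits the
ground truth (true rates, true node states, the withheld and renamed tips)
needed to score downstream estimates.

The generator emulates the statistical structure of a karyotype survey
joined to a time-calibrated phylogeny: states are the fusion classes only
(no chromosome numbers or morphology), genera are contiguous blocks of tips
in traversal order (a stylised but phylogenetically plausible choice), and
missingness is uniform at random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import dendropy
import numpy as np
import pandas as pd

from .mk import FOUR_STATES, SIX_STATE_FUSION, Phylogeny, RateModel, simulate_characters

__all__ = ["TreeSimConfig", "DatasetSimConfig", "simulate_tree",
           "assign_genera", "simulate_dataset", "DEFAULT_TRUE_RATES"]

#: default four-state generating rates: fusions arise 20x faster in XY than
#: ZW systems, fissions are shared, heterogamety turnover is symmetric.
#: With the shared fission rate these give stationary fused fractions of
#: ~50% within XY and ~5% within ZW lineages, matching the prevalence
#: pattern seen in vertebrate karyotype surveys, and the turnover keeps both
#: heterogamety systems represented on trees of height ~log(n_tips).
DEFAULT_TRUE_RATES: Dict[str, float] = {
    "q_XY.XYF": 0.1, "q_ZW.ZWF": 0.005,
    "q_XYF.XY": 0.1, "q_ZWF.ZW": 0.1,
    "q_XY.ZW": 0.15, "q_ZW.XY": 0.15,
}


@dataclass(frozen=True)
class TreeSimConfig:
    """Constant-rate birth-death simulation conditioned on the number of
    surviving tips.  Time units are arbitrary; rates are per lineage per
    unit time."""

    n_tips: int
    birth_rate: float = 1.0
    death_rate: float = 0.0
    seed: int = 0
    ultrametrize: bool = True

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be at least 2")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("birth rate must be positive, death rate non-negative")


def simulate_tree(config: TreeSimConfig) -> Phylogeny:
    """Forward birth-death simulation, restarted on extinction, stopped the
    first time the extant count reaches ``n_tips``.

    Pendant edges are extended by the waiting time to the (unrealised) next
    event, so for a pure-birth process the expected root height is
    (1/lambda) * (sum_{k=2}^{n-1} 1/k + 1/n), which the tests check.
    The returned tree contains only the surviving lineages and is
    ultrametric by construction.
    """
    rng = np.random.default_rng(config.seed)
    lam, mu = config.birth_rate, config.death_rate
    n_target = config.n_tips

    while True:
        tree = dendropy.Tree()
        root = tree.seed_node
        active: List[Tuple[dendropy.Node, float]] = [(root, 0.0)]
        dead: List[dendropy.Node] = []
        t = 0.0
        counter = 0
        while active and len(active) < n_target:
            n_act = len(active)
            total = n_act * (lam + mu)
            t += rng.exponential(1.0 / total)
            i = int(rng.integers(n_act))
            node, attach = active.pop(i)
            if node is not root:
                node.edge.length = t - attach
            if rng.random() < lam / (lam + mu):
                c1, c2 = dendropy.Node(), dendropy.Node()
                node.add_child(c1)
                node.add_child(c2)
                active.append((c1, t))
                active.append((c2, t))
            else:
                dead.append(node)
        if not active:
            continue  # clade went extinct; retry
        u = rng.exponential(1.0 / (n_target * (lam + mu)))
        t_end = t + u
        taxon_ns = tree.taxon_namespace
        survivors = []
        for node, attach in active:
            if node is not root:
                node.edge.length = t_end - attach
            counter += 1
            label = f"t{counter}"
            node.taxon = taxon_ns.new_taxon(label=label)
            survivors.append(label)
        for node in dead:
            counter += 1
            node.taxon = taxon_ns.new_taxon(label=f"dead{counter}")
        if dead:
            tree.retain_taxa_with_labels(survivors)
        tree.suppress_unifurcations()
        phy = Phylogeny(tree)
        if phy.n_tips != n_target:
            continue
        if config.ultrametrize:
            _make_exactly_ultrametric(phy)
        return phy


def _make_exactly_ultrametric(phy: Phylogeny) -> None:
    """Absorb floating-point drift by stretching pendant edges so all
    root-to-tip distances equal their maximum."""
    tree = phy.dendropy_tree
    tree.calc_node_ages(ultrametricity_precision=False)
    depths = {leaf: leaf.distance_from_root() for leaf in tree.leaf_node_iter()}
    target = max(depths.values())
    for leaf, d in depths.items():
        leaf.edge.length += target - d
    phy._index()


def assign_genera(n_tips: int, mean_genus_size: float,
                  rng: np.random.Generator) -> List[int]:
    """Partition ``n_tips`` traversal-adjacent tips into genera with
    geometric sizes of the given mean; returns the genus index per tip."""
    if mean_genus_size < 1:
        raise ValueError("mean genus size must be >= 1")
    p = 1.0 / mean_genus_size
    out: List[int] = []
    g = 0
    while len(out) < n_tips:
        size = int(rng.geometric(p))
        out.extend([g] * size)
        g += 1
    return out[:n_tips]


@dataclass(frozen=True)
class DatasetSimConfig:
    """Full dataset generation: tree + characters + genus-structured labels
    + controlled missingness.

    ``missing_frac`` tips are dropped from the trait table (they must be
    pruned downstream); ``mismatch_frac`` tips are renamed in the tree to a
    congeneric pseudo-species while the table keeps the original name (they
    must be recovered by genus substitution); ``ambiguous_frac`` table rows
    have their fusion state masked (uniform tip row downstream).

    ``min_minority_frac`` > 0 redraws the character history until both
    heterogamety systems each hold at least that fraction of tips.  This
    mirrors the empirical study design, which targets clades segregating for
    many independent origins of both XY and ZW systems; datasets dominated
    by a single system carry almost no information about the rarer system's
    fusion rate.
    """

    tree: TreeSimConfig
    model: RateModel = field(default_factory=RateModel.four_state)
    true_rates: Optional[Dict[str, float]] = None
    mean_genus_size: float = 3.0
    missing_frac: float = 0.1
    mismatch_frac: float = 0.1
    ambiguous_frac: float = 0.02
    min_minority_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_frac", "mismatch_frac", "ambiguous_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def rates(self) -> Dict[str, float]:
        if self.true_rates is not None:
            return dict(self.true_rates)
        if tuple(self.model.states) == FOUR_STATES:
            return {name: DEFAULT_TRUE_RATES.get(name, 0.02)
                    for name in self.model.param_names}
        return {name: 0.05 for name in self.model.param_names}


def _state_to_columns(state: str) -> Tuple[str, str]:
    """Map a model state to (heterogamety, fusion) table values."""
    if state in ("XY", "ZW"):
        return state, "none"
    if state == "XYF":
        return "XY", "YA"  # four-state model does not resolve the partner;
        # the Y-A class is the overwhelmingly common fused state empirically
    if state == "ZWF":
        return "ZW", "WA"
    fusion = SIX_STATE_FUSION.get(state)
    if fusion is None:
        raise ValueError(f"unknown state {state}")
    het = "XY" if state in ("X1X2Y", "XY1Y2") else "ZW"
    return het, fusion


def simulate_dataset(config: DatasetSimConfig):
    """Generate (tree, species table, truth dict).

    The truth dict records the true rates, the root and internal node
    states, and exactly which tips were withheld, renamed, or masked, so
    every downstream estimate (rates, matching decisions, state
    reconstructions) can be scored.
    """
    rng = np.random.default_rng(config.seed)
    tree_cfg = TreeSimConfig(
        n_tips=config.tree.n_tips, birth_rate=config.tree.birth_rate,
        death_rate=config.tree.death_rate,
        seed=int(rng.integers(2**31 - 1)), ultrametrize=config.tree.ultrametrize)
    phy = simulate_tree(tree_cfg)

    # genus-structured binomial names in traversal order
    genus_of = assign_genera(phy.n_tips, config.mean_genus_size, rng)
    rename: Dict[str, str] = {}
    sp_counter: Dict[int, int] = {}
    species: List[str] = []
    for tip, g in zip(phy.tip_labels, genus_of):
        sp_counter[g] = sp_counter.get(g, 0) + 1
        name = f"G{g + 1:04d}_sp{sp_counter[g]:02d}"
        rename[tip] = name
        species.append(name)
    phy = phy.rename_tips(rename)

    rates = config.rates()
    values = [rates[name] for name in config.model.param_names]
    xy_like = [s for s in config.model.states if s.startswith("X")]
    for _attempt in range(50):
        tips, node_states = simulate_characters(
            phy, config.model, values, seed=int(rng.integers(2**31 - 1)))
        if config.min_minority_frac <= 0:
            break
        frac_xy = float(tips[xy_like].to_numpy().sum()) / phy.n_tips
        if config.min_minority_frac <= frac_xy <= 1.0 - config.min_minority_frac:
            break
    else:
        raise RuntimeError("could not draw a character history with both "
                           "heterogamety systems sufficiently represented")

    state_of = {label: config.model.states[int(np.argmax(tips.loc[label].to_numpy()))]
                for label in phy.tip_labels}
    rows = []
    for label in phy.tip_labels:
        het, fus = _state_to_columns(state_of[label])
        rows.append({"species": label, "genus": label.split("_")[0],
                     "heterogamety": het, "fusion": fus, "flag": ""})
    table = pd.DataFrame(rows)

    n = phy.n_tips
    order = rng.permutation(n)
    n_missing = int(round(config.missing_frac * n))
    n_mismatch = int(round(config.mismatch_frac * n))
    n_ambiguous = int(round(config.ambiguous_frac * n))
    missing = [phy.tip_labels[i] for i in order[:n_missing]]
    mismatched = [phy.tip_labels[i] for i in order[n_missing:n_missing + n_mismatch]]
    ambiguous = [phy.tip_labels[i]
                 for i in order[n_missing + n_mismatch:
                                n_missing + n_mismatch + n_ambiguous]]

    table = table[~table["species"].isin(missing)].reset_index(drop=True)
    table.loc[table["species"].isin(ambiguous), "fusion"] = "unknown"

    # rename mismatched tips in the TREE only: the table keeps the original
    # species, which downstream matching must recover via the genus rule
    tree_rename = {sp: f"{sp.split('_')[0]}_x{j + 1:02d}"
                   for j, sp in enumerate(mismatched)}
    phy_out = phy.rename_tips(tree_rename)

    truth = {
        "true_rates": rates,
        "states": {"model": list(config.model.states)},
        "tip_states": state_of,
        "node_states": {str(k): v for k, v in node_states.items()},
        "missing_tips": missing,
        "mismatched_tips": tree_rename,
        "ambiguous_species": ambiguous,
        "tree_seed": tree_cfg.seed,
    }
    return phy_out, table, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
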