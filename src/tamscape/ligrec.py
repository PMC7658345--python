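"""Ligand-receptor co-expression analysis and loop-importance ranking.

Ligand and receptor panels are filtered to genes expressed (count > 0) by at
least 5% of cells; receptors enter via a ligand-receptor pair table (FANTOM
style, two-column TSV).  A layered "hive" graph is built with activation
states, ligands and receptors as node layers and edges

    state -> ligand    weight = fraction of the state's cells expressing the ligand
    ligand -> receptor weight = 1 per pair-table edge
    receptor -> state  weight = fraction of the state's cells expressing the receptor

The importance of a receptor within a state is proportional to the sum of
edge weights over all 3-edge loops state -> ligand -> receptor -> state that
pass through it (additive loop-weight convention; a multiplicative
convention is available behind ``loop_weight='product'``).  Ligand
importance is defined symmetrically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import mannwhitney
from .ingest import CountMatrix, expression_fraction


@dataclass
class PairTable:
    pairs: pd.DataFrame  # columns ligand, receptor

    def __post_init__(self):
        df = self.pairs
        if list(df.columns[:2]) != ["ligand", "receptor"]:
            df = df.iloc[:, :2].set_axis(["ligand", "receptor"], axis=1)
        if df.duplicated().any():
            raise ValueError("duplicate (ligand, receptor) rows in pair table")
        self.pairs = df.reset_index(drop=True)

    @classmethod
    def read(cls, path) -> "PairTable":
        return cls(pd.read_csv(Path(path), sep="\t"))

    def receptors_for(self, ligand: str) -> list:
        return list(self.pairs.loc[self.pairs["ligand"] == ligand, "receptor"])

    def ligands_for(self, receptor: str) -> list:
        return list(self.pairs.loc[self.pairs["receptor"] == receptor, "ligand"])


@dataclass
class LigRecGraph:
    states: list
    ligands: list
    receptors: list
    w_state_ligand: pd.DataFrame  # states x ligands
    w_ligand_receptor: pd.DataFrame  # ligands x receptors (0/1 pairing by default)
    w_receptor_state: pd.DataFrame  # receptors x states

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for s in self.states:
            for l in self.ligands:
                rows.append((s, l, "state-ligand", self.w_state_ligand.at[s, l]))
        for l in self.ligands:
            for r in self.receptors:
                w = self.w_ligand_receptor.at[l, r]
                if w > 0:
                    rows.append((l, r, "ligand-receptor", w))
        for r in self.receptors:
            for s in self.states:
                rows.append((r, s, "receptor-state", self.w_receptor_state.at[r, s]))
        return pd.DataFrame(rows, columns=["src", "dst", "layer", "weight"])


def filter_panel(m: CountMatrix, genes, min_frac: float = 0.05) -> list:
    """Genes expressed by at least `min_frac` of cells, in input order."""
    frac = expression_fraction(m, list(genes))
    kept = [g for g in genes if frac[g] >= min_frac]
    if not kept:
        warnings.warn("no panel gene passes the expression-fraction filter")
    return kept


def pair_receptors(ligands, pairs: PairTable, m: CountMatrix, min_frac: float = 0.05) -> list:
    """Receptors partnered with any retained ligand, then expression-filtered."""
    seen = set()
    candidates = []
    for l in ligands:
        for r in pairs.receptors_for(l):
            if r not in seen:
                seen.add(r)
                candidates.append(r)
    return filter_panel(m, candidates, min_frac)


def per_cell_density(m: CountMatrix, panel) -> np.ndarray:
    """Number of panel genes with count > 0 in each cell."""
    if len(panel) == 0:
        raise ValueError("panel is empty")
    lookup = {g: i for i, g in enumerate(m.gene_ids)}
    idx = [lookup[g] for g in panel if g in lookup]
    dense = m.dense()
    present = np.zeros(m.n_cells, dtype=int)
    if idx:
        present = (dense[idx, :] > 0).sum(axis=0)
    return np.asarray(present).ravel()


def density_by_group(densities, groups, contrast) -> tuple:
    """Mean density per contrast side plus a two-sided Mann-Whitney p."""
    densities = np.asarray(densities, dtype=float)
    groups = np.asarray(groups, dtype=object)
    set_a, set_b = contrast
    in_a = np.isin(groups, list(set_a))
    in_b = np.isin(groups, list(set_b))
    if not in_a.any() or not in_b.any():
        raise ValueError("both contrast sides must contain cells")
    xa, xb = densities[in_a], densities[in_b]
    return float(xa.mean()), float(xb.mean()), mannwhitney(xa, xb)


def _expression_fraction_by_state(m: CountMatrix, states, panel) -> pd.DataFrame:
    states = np.asarray(states, dtype=object)
    uniq = list(pd.unique(states))
    out = pd.DataFrame(0.0, index=uniq, columns=list(panel))
    for s in uniq:
        idx = np.where(states == s)[0]
        if idx.size == 0:
            warnings.warn(f"state {s!r} has no cells; its edge weights are 0")
            continue
        sub = m.subset_cells(idx)
        out.loc[s] = expression_fraction(sub, list(panel)).values
    return out


def build_graph(m: CountMatrix, states, ligands, receptors, pairs: PairTable) -> LigRecGraph:
    """Layered state/ligand/receptor graph with expression-fraction edge weights."""
    states_arr = np.asarray(states, dtype=object)
    uniq_states = list(pd.unique(states_arr))
    w_sl = _expression_fraction_by_state(m, states_arr, ligands)
    w_rs = _expression_fraction_by_state(m, states_arr, receptors).T
    w_lr = pd.DataFrame(0.0, index=list(ligands), columns=list(receptors))
    for _, row in pairs.pairs.iterrows():
        if row["ligand"] in w_lr.index and row["receptor"] in w_lr.columns:
            w_lr.at[row["ligand"], row["receptor"]] = 1.0
    return LigRecGraph(uniq_states, list(ligands), list(receptors), w_sl, w_lr, w_rs)


def loop_importance(
    g: LigRecGraph, node: str, state: str, loop_weight: str = "sum"
) -> float:
    """Summed weight of all 3-edge loops state -> ligand -> receptor -> state through `node`.

    With ``loop_weight='sum'`` (default) a loop contributes the sum of its
    three edge weights; with ``'product'`` it contributes their product.
    """
    if state not in g.states:
        raise KeyError(f"unknown state {state!r}")
    if node in g.receptors:
        partners = [l for l in g.ligands if g.w_ligand_receptor.at[l, node] > 0]
        triples = [
            (g.w_state_ligand.at[state, l], g.w_ligand_receptor.at[l, node],
             g.w_receptor_state.at[node, state])
            for l in partners
        ]
    elif node in g.ligands:
        partners = [r for r in g.receptors if g.w_ligand_receptor.at[node, r] > 0]
        triples = [
            (g.w_state_ligand.at[state, node], g.w_ligand_receptor.at[node, r],
             g.w_receptor_state.at[r, state])
            for r in partners
        ]
    else:
        raise KeyError(f"node {node!r} is neither a ligand nor a receptor in the graph")
    if loop_weight == "sum":
        return float(sum(sum(t) for t in triples))
    if loop_weight == "product":
        return float(sum(t[0] * t[1] * t[2] for t in triples))
    raise ValueError("loop_weight must be 'sum' or 'product'")


def rank_nodes(g: LigRecGraph, state: str, loop_weight: str = "sum") -> pd.DataFrame:
    """Receptors and ligands ranked by descending loop importance within a state.

    Ties share the smaller rank ("competition" ranking); the secondary sort
    key is the node id, so output order is deterministic.
    """
    rows = []
    for layer, nodes in (("receptor", g.receptors), ("ligand", g.ligands)):
        imps = [(n, loop_importance(g, n, state, loop_weight)) for n in nodes]
        imps.sort(key=lambda t: (-t[1], t[0]))
        ranks = []
        for i, (n, imp) in enumerate(imps):
            if i > 0 and imp == imps[i - 1][1]:
                ranks.append(ranks[-1])
            else:
                ranks.append(i + 1)
        for (n, imp), r in zip(imps, ranks):
            rows.append({"node": n, "layer": layer, "state": state,
                         "importance": imp, "rank": r})
    return pd.DataFrame(rows)
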