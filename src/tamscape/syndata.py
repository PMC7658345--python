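"""Synthetic single-cell and bulk data with the study's statistical structure.

The generator emulates a regional glioblastoma TAM dataset: negative-binomial
counts for cells split into tumour core and periphery, with disjoint gene
blocks carrying the planted programs —

* ontogeny blocks (BMDM-like vs microglia-like) whose means scale with a
  per-cell ontogeny fraction drawn high in core and low in periphery,
* a differentiation block rising with a latent branched trajectory's time,
* a polarization block rising with time on branch A and falling on branch B,
* ligand/receptor panels expressed more by immature activation states,
* pathway-1 genes loading only on branch A (rising) and pathway-2 genes
  loading only on the terminal segment of branch B,
* background genes sharing one baseline mean (so signature nulls are exact).

Cells follow a Y-shaped latent trajectory: latent time uniform on [0, 1],
trunk before ``trajectory_branch_time``, then a fair coin picks branch A or
B.  True activation states come from the quadrant of (maturity,
polarization).  Counts are NB2 with shared dispersion and expected library
size ``depth_mean`` per cell; everything is driven by one seeded generator,
so identical configs give bit-identical output.

Bulk samples are weighted mixtures of single-cell profiles labelled with the
five Ivy-style anatomic structures (periphery-type structures draw >= 80%
of their cells from periphery, core-type from core).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .ingest import CountMatrix
from .scores import GeneSignature

PROGRAMS = (
    "ontogeny-BMDM",
    "ontogeny-MG",
    "polarization",
    "differentiation",
    "ligand",
    "receptor",
    "pathway-1",
    "pathway-2",
)

IVY_STRUCTURES = (
    "leading edge",
    "infiltrating tumour",
    "cellular tumour",
    "microvascular proliferation",
    "pseudopalisading cells",
)
PERIPHERY_STRUCTURES = ("leading edge", "infiltrating tumour")

# branch B polarization declines at half the branch A rise, so the
# population-level polarization trend keeps the wiring's sign
BRANCH_B_SLOPE = 0.5
# terminal fraction of branch B where pathway-2 switches on
PATHWAY2_ONSET = 0.6


def _default_signature_sizes() -> dict:
    return {
        "ontogeny-BMDM": 40,
        "ontogeny-MG": 40,
        "polarization": 40,
        "differentiation": 40,
        "ligand": 20,
        "receptor": 30,
        "pathway-1": 40,
        "pathway-2": 40,
    }


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    ``polarization_wiring`` (+1/-1) flips the sign of the polarization
    program's coupling to the trajectory, emulating the core-like
    (pro-inflammatory with maturation, +1) vs periphery-like (-1) regimes.
    """

    n_cells_core: int = 2343
    n_cells_periphery: int = 1246
    n_genes: int = 2000
    nb_dispersion: float = 0.5
    depth_mean: float = 2000.0
    signature_sizes: dict = field(default_factory=_default_signature_sizes)
    trajectory_branch_time: float = 0.5
    effect_size: float = 1.0
    polarization_wiring: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_cells_core <= 0 or self.n_cells_periphery <= 0 or self.n_genes <= 0:
            raise ValueError("cell and gene counts must be positive")
        if not (0.0 < self.trajectory_branch_time < 1.0):
            raise ValueError("trajectory_branch_time must lie strictly inside (0, 1)")
        if self.nb_dispersion <= 0 or self.depth_mean <= 0:
            raise ValueError("nb_dispersion and depth_mean must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if sum(self.signature_sizes.values()) >= self.n_genes:
            raise ValueError("signature blocks must leave room for background genes")


@dataclass
class SyntheticTruth:
    latent_time: np.ndarray  # per cell, in [0, 1]
    branch_id: np.ndarray  # trunk / A / B
    ontogeny_fraction: np.ndarray  # 1 = pure BMDM-like
    activation_state_true: np.ndarray
    program_membership: pd.Series  # gene -> program label (incl. background)

    def genes_of(self, program: str) -> list:
        return list(self.program_membership.index[self.program_membership == program])

    def signature(self, program: str, name: str | None = None) -> GeneSignature:
        return GeneSignature(name or program, self.genes_of(program))


def default_signatures(truth: SyntheticTruth) -> dict:
    """Ready-made signatures for scoring the synthetic data.

    Negative (reference) signatures for the MPI/AMDI surrogate are disjoint
    background slices, so their meta-gene scores are null by construction.
    """
    bg = truth.genes_of("background")
    return {
        "bmdm": truth.signature("ontogeny-BMDM", "bmdm"),
        "mg": truth.signature("ontogeny-MG", "mg"),
        "pol_pos": truth.signature("polarization", "pol_pos"),
        "pol_neg": GeneSignature("pol_neg", bg[:40]),
        "dif_pos": truth.signature("differentiation", "dif_pos"),
        "dif_neg": GeneSignature("dif_neg", bg[40:80]),
        "pathway1": truth.signature("pathway-1", "pathway1"),
        "pathway2": truth.signature("pathway-2", "pathway2"),
        "ligand": truth.signature("ligand", "ligand"),
        "receptor": truth.signature("receptor", "receptor"),
    }


def default_pair_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Ligand-receptor pair table over the synthetic panels (round-robin pairing)."""
    ligs = truth.genes_of("ligand")
    recs = truth.genes_of("receptor")
    rows = [
        {"ligand": ligs[i % len(ligs)], "receptor": r} for i, r in enumerate(recs)
    ]
    return pd.DataFrame(rows)


def _program_labels(config: SynthConfig) -> pd.Series:
    labels = []
    genes = []
    i = 0
    for prog in PROGRAMS:
        size = config.signature_sizes.get(prog, 0)
        for _ in range(size):
            genes.append(f"G{i:05d}")
            labels.append(prog)
            i += 1
    while i < config.n_genes:
        genes.append(f"G{i:05d}")
        labels.append("background")
        i += 1
    return pd.Series(labels, index=genes, name="program")


def _latent_drivers(config: SynthConfig, rng: np.random.Generator, n_cells: int, regions):
    bt = config.trajectory_branch_time
    t = rng.uniform(0.0, 1.0, n_cells)
    branch = np.where(t < bt, "trunk",
                      np.where(rng.random(n_cells) < 0.5, "A", "B")).astype(object)
    is_core = np.asarray(regions) == "core"
    frac = np.where(is_core, rng.beta(8, 2, n_cells), rng.beta(2, 8, n_cells))
    prog = np.clip((t - bt) / (1.0 - bt), 0.0, None)  # progress past the branch point
    pol = np.where(branch == "A", prog, np.where(branch == "B", -BRANCH_B_SLOPE * prog, 0.0))
    pol = config.polarization_wiring * pol
    # latent quadrant: mature past the branch point, polarized by sign of
    # pol (trunk cells get small polarization noise so all four states occur)
    pol_noisy = pol + rng.normal(0.0, 0.15, n_cells)
    mature = t >= bt
    state = np.where(
        mature,
        np.where(pol_noisy > 0, "M1-like", "M2-like"),
        np.where(pol_noisy > 0, "M1-pre", "M0"),
    ).astype(object)
    return t, branch, frac, pol, state


def generate_single_cell(config: SynthConfig) -> tuple:
    """Draw a (CountMatrix, SyntheticTruth) pair under the planted model."""
    rng = np.random.default_rng(config.seed)
    n_cells = config.n_cells_core + config.n_cells_periphery
    regions = np.array(
        ["core"] * config.n_cells_core + ["periphery"] * config.n_cells_periphery,
        dtype=object,
    )
    tumor = np.array([f"T{1 + (i % 4)}" for i in range(n_cells)], dtype=object)
    cell_ids = np.array(
        [f"{r[:4]}_{i:05d}" for i, r in enumerate(regions)], dtype=object
    )
    program = _program_labels(config)
    t, branch, frac, pol, state = _latent_drivers(config, rng, n_cells, regions)
    bt = config.trajectory_branch_time
    prog_b = np.clip((t - bt) / (1.0 - bt), 0.0, None)
    immature = np.isin(state, ["M0", "M1-pre"]).astype(float)

    drivers = {
        "ontogeny-BMDM": frac,
        "ontogeny-MG": 1.0 - frac,
        "differentiation": t,
        "polarization": pol,  # in [-1, 1]: below baseline on the down branch
        "ligand": 0.7 * immature,
        "receptor": 0.7 * immature,
        "pathway-1": np.where(branch == "A", prog_b, 0.0),
        "pathway-2": np.where(
            (branch == "B") & (prog_b >= PATHWAY2_ONSET), 1.0, 0.0
        ),
    }
    log_mean = np.zeros((config.n_genes, n_cells))
    for prog_name, driver in drivers.items():
        sel = (program.values == prog_name)
        if sel.any():
            log_mean[sel, :] = config.effect_size * driver[None, :]
    mean = np.exp(log_mean)
    p_rel = mean / mean.sum(axis=0, keepdims=True)
    mu = config.depth_mean * p_rel
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    meta = pd.DataFrame(
        {"region": regions, "tumor_id": tumor}, index=pd.Index(cell_ids, name="cell_id")
    )
    cm = CountMatrix(sp.csr_matrix(counts), program.index.values.copy(), meta)
    truth = SyntheticTruth(t, branch, frac, state, program)
    return cm, truth


def generate_bulk(
    config: SynthConfig,
    sc: CountMatrix,
    truth: SyntheticTruth,
    n_samples_per_region: int = 5,
    cells_per_sample: int = 200,
    dominant_weight: float = 0.9,
) -> tuple:
    """Bulk samples as weighted mixtures of single-cell profiles.

    Each sample averages the counts of ``cells_per_sample`` cells drawn with
    replacement, with probability mass ``dominant_weight`` on the matching
    region (periphery for leading edge / infiltrating tumour, core for the
    other three structures).  Returns (genes x samples DataFrame, Series of
    structure labels per sample).
    """
    if n_samples_per_region < 1:
        raise ValueError("n_samples_per_region must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    dense = sc.dense().astype(float)
    regions = np.asarray(sc.cell_meta["region"], dtype=object)
    is_peri = regions == "periphery"
    cols = {}
    labels = {}
    for structure in IVY_STRUCTURES:
        target_peri = structure in PERIPHERY_STRUCTURES
        w = np.where(is_peri == target_peri, dominant_weight, 1.0 - dominant_weight)
        w = w / w.sum()
        for j in range(n_samples_per_region):
            name = f"{structure.replace(' ', '_')}_{j}"
            idx = rng.choice(len(w), size=cells_per_sample, replace=True, p=w)
            cols[name] = dense[:, idx].mean(axis=1)
            labels[name] = structure
    table = pd.DataFrame(cols, index=sc.gene_ids)
    return table, pd.Series(labels, name="structure")
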