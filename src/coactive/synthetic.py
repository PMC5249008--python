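"""Synthetic scRNA-seq count matrices with planted ground truth.

The generator emulates the generative structure the calling pipeline assumes:
per gene, a cell's log2CPM value is zero with a dropout probability, and
otherwise drawn from the gamma (low) component or the normal (high/active)
component according to a per-gene mixing weight.  On top of this background
the generator can plant

* maturity structure: two mutually exclusive anchor markers (OMP active in
  mature cells, GAP43 in immature cells) and marker genes whose activity
  probability contrasts between the two groups; and
* per-cell network topology: "star" cells carrying one private gene coactive
  with a block of shared genes (hub-partner topology after prevalence
  filtering) versus "dense" cells carrying a clique of private genes.

Drawn log2CPM values are back-converted to integer counts with a nominal
library size of one million, r = round((2^y - 1)), so that re-applying the
pipeline's own log2CPM transform approximately recovers the drawn values.
Truth tables record every latent state, group label and planted role, which
is sufficient to score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: minimum log2CPM value emitted for a non-zero state (keeps the zero pattern
#: of the truth intact after rounding to integer counts)
_MIN_POSITIVE = 0.05


@dataclass(frozen=True)
class MarkerPlan:
    """Planted maturity structure.

    Cells are split into ``n_mature_cells`` mature, ``n_immature_cells``
    immature and the remainder unlabelled.  The mature anchor is active in
    exactly the mature cells and the immature anchor in exactly the immature
    cells.  Planted associated genes are active with probability
    ``p_active_own`` in their own group and ``p_active_other`` in the other.
    """

    mature_marker: str = "OMP"
    immature_marker: str = "GAP43"
    n_mature_cells: int = 60
    n_immature_cells: int = 60
    n_mature_assoc: int = 20
    n_immature_assoc: int = 0
    p_active_own: float = 0.8
    p_active_other: float = 0.1


@dataclass(frozen=True)
class NetworkPlan:
    """Planted per-cell coactivation topology.

    Star cells (taken from the mature group) are active for one private gene
    plus ``n_shared_genes`` shared genes; after prevalence filtering the
    shared-shared edges are population-prevalent and drop out, leaving a star
    centred on the private gene.  Dense cells (from the immature group) are
    active for ``n_private_per_dense`` genes unique to that cell, whose
    clique survives filtering intact.  Planted genes receive low-expression
    values in a ``background_nonzero_prob`` fraction of other cells so the
    mixture remains fittable.
    """

    n_star_cells: int = 50
    n_dense_cells: int = 50
    n_shared_genes: int = 9
    n_private_per_dense: int = 9
    background_nonzero_prob: float = 0.3


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Background per-gene parameters may be scalars (broadcast to all genes) or
    arrays of length ``n_genes``.  Defaults describe a typical deeply
    zero-inflated scRNA-seq gene: 60% dropout, low component Gamma(2, 2) and
    high component Normal(8, 1) on the log2CPM scale with mixing weight 0.4.
    """

    n_genes: int = 500
    n_cells: int = 120
    zero_prob: float | np.ndarray = 0.6
    gamma_shape: float | np.ndarray = 2.0
    gamma_rate: float | np.ndarray = 2.0
    normal_mean: float | np.ndarray = 8.0
    normal_sd: float | np.ndarray = 1.0
    rho: float | np.ndarray = 0.4
    marker_plan: MarkerPlan | None = None
    network_plan: NetworkPlan | None = None
    seed: int = 0


@dataclass
class TruthTables:
    """Latent truth for a generated dataset.

    ``states`` holds the true per-gene per-cell state (0 zero, 1 low,
    2 high/active); ``cell_group`` maps each cell to mature / immature /
    other; ``network_role`` maps each cell to star / dense / none.
    """

    states: pd.DataFrame
    cell_group: pd.Series
    network_role: pd.Series
    mature_assoc_genes: list[str] = field(default_factory=list)
    immature_assoc_genes: list[str] = field(default_factory=list)
    anchors: tuple[str, str] | None = None

    @property
    def activity(self) -> pd.DataFrame:
        """True binary activity matrix (state == 2)."""
        return (self.states == 2).astype(float)


def sample_mixture(n: int, alpha, beta, mu, sigma, rho, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw n positive values from the gamma-normal mixture.

    Returns (values, component) with component 1 for gamma/low and 2 for
    normal/high.  Normal draws are clipped away from zero so every value is
    strictly positive, as non-zero log2CPM values are.
    """
    high = rng.random(n) < rho
    x = np.empty(n)
    x[~high] = rng.gamma(shape=alpha, scale=1.0 / beta, size=int((~high).sum()))
    x[high] = rng.normal(mu, sigma, size=int(high.sum()))
    x = np.maximum(x, _MIN_POSITIVE)
    return x, np.where(high, 2, 1)


def _broadcast(value, n: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
    if name in {"zero_prob", "rho"} and ((arr < 0) | (arr > 1)).any():
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def _plan_gene_names(spec: SyntheticSpec) -> tuple[list[str], dict[str, list[str]]]:
    """Assign roles to gene slots; planted genes occupy the head of the matrix."""
    roles: dict[str, list[str]] = {
        "mature_assoc": [],
        "immature_assoc": [],
        "shared": [],
        "star_private": [],
        "dense_private": [],
    }
    names: list[str] = []
    mp, np_ = spec.marker_plan, spec.network_plan
    if mp is not None:
        names += [mp.mature_marker, mp.immature_marker]
        roles["mature_assoc"] = [f"matA{i:03d}" for i in range(mp.n_mature_assoc)]
        roles["immature_assoc"] = [f"immA{i:03d}" for i in range(mp.n_immature_assoc)]
        names += roles["mature_assoc"] + roles["immature_assoc"]
    if np_ is not None:
        roles["shared"] = [f"hub{i:03d}" for i in range(np_.n_shared_genes)]
        roles["star_private"] = [f"starP{i:03d}" for i in range(np_.n_star_cells)]
        roles["dense_private"] = [
            f"denseP{c:03d}_{g:02d}"
            for c in range(np_.n_dense_cells)
            for g in range(np_.n_private_per_dense)
        ]
        names += roles["shared"] + roles["star_private"] + roles["dense_private"]
    if len(names) > spec.n_genes:
        raise ValueError(
            f"planted structure needs {len(names)} genes but n_genes={spec.n_genes}"
        )
    names += [f"gene{i:05d}" for i in range(spec.n_genes - len(names))]
    return names, roles


def generate(spec: SyntheticSpec) -> tuple[pd.DataFrame, TruthTables]:
    """Generate a counts matrix and its latent truth from the study spec."""
    n_genes, n_cells = spec.n_genes, spec.n_cells
    rng = np.random.default_rng(spec.seed)
    gene_names, roles = _plan_gene_names(spec)
    cell_names = [f"cell{j:05d}" for j in range(n_cells)]

    zero_prob = _broadcast(spec.zero_prob, n_genes, "zero_prob")
    shape = _broadcast(spec.gamma_shape, n_genes, "gamma_shape")
    rate = _broadcast(spec.gamma_rate, n_genes, "gamma_rate")
    mean = _broadcast(spec.normal_mean, n_genes, "normal_mean")
    sd = _broadcast(spec.normal_sd, n_genes, "normal_sd")
    rho = _broadcast(spec.rho, n_genes, "rho")

    # background states: 0 with dropout prob, else low/high by rho
    u = rng.random((n_genes, n_cells))
    high = rng.random((n_genes, n_cells)) < rho[:, None]
    states = np.where(u < zero_prob[:, None], 0, np.where(high, 2, 1))

    gene_idx = {g: i for i, g in enumerate(gene_names)}
    cell_group = np.array(["other"] * n_cells, dtype=object)
    network_role = np.array(["none"] * n_cells, dtype=object)
    mp, nplan = spec.marker_plan, spec.network_plan

    if mp is not None:
        if mp.n_mature_cells + mp.n_immature_cells > n_cells:
            raise ValueError("marker plan needs more cells than n_cells")
        mat = np.arange(mp.n_mature_cells)
        imm = np.arange(mp.n_mature_cells, mp.n_mature_cells + mp.n_immature_cells)
        cell_group[mat] = "mature"
        cell_group[imm] = "immature"

        def _overwrite(gene: str, active_mask: np.ndarray) -> None:
            i = gene_idx[gene]
            inactive = ~active_mask
            states[i, active_mask] = 2
            # inactive cells fall back to dropout-or-low
            drop = rng.random(int(inactive.sum())) < zero_prob[i]
            states[i, inactive] = np.where(drop, 0, 1)

        anchor_mat = np.zeros(n_cells, dtype=bool)
        anchor_mat[mat] = True
        anchor_imm = np.zeros(n_cells, dtype=bool)
        anchor_imm[imm] = True
        _overwrite(mp.mature_marker, anchor_mat)
        _overwrite(mp.immature_marker, anchor_imm)

        for gene in roles["mature_assoc"]:
            p = np.full(n_cells, spec.rho if np.isscalar(spec.rho) else 0.0)
            p[mat] = mp.p_active_own
            p[imm] = mp.p_active_other
            _overwrite(gene, rng.random(n_cells) < p)
        for gene in roles["immature_assoc"]:
            p = np.full(n_cells, spec.rho if np.isscalar(spec.rho) else 0.0)
            p[imm] = mp.p_active_own
            p[mat] = mp.p_active_other
            _overwrite(gene, rng.random(n_cells) < p)

    if nplan is not None:
        if mp is None:
            raise ValueError("network_plan requires a marker_plan to define groups")
        if nplan.n_star_cells > mp.n_mature_cells:
            raise ValueError("more star cells than mature cells")
        if nplan.n_dense_cells > mp.n_immature_cells:
            raise ValueError("more dense cells than immature cells")
        star_cells = np.arange(nplan.n_star_cells)
        dense_cells = mp.n_mature_cells + np.arange(nplan.n_dense_cells)
        network_role[star_cells] = "star"
        network_role[dense_cells] = "dense"

        def _planted(gene: str, active_cells: np.ndarray) -> None:
            i = gene_idx[gene]
            bg = rng.random(n_cells) < nplan.background_nonzero_prob
            states[i, :] = np.where(bg, 1, 0)
            states[i, active_cells] = 2

        for g in roles["shared"]:
            _planted(g, star_cells)
        for c, g in zip(star_cells, roles["star_private"]):
            _planted(g, np.array([c]))
        k = nplan.n_private_per_dense
        for ci, c in enumerate(dense_cells):
            for g in roles["dense_private"][ci * k : (ci + 1) * k]:
                _planted(g, np.array([c]))

    # draw log2CPM values for the non-zero states
    y = np.zeros((n_genes, n_cells))
    low_mask = states == 1
    high_mask = states == 2
    for i in range(n_genes):
        nl, nh = int(low_mask[i].sum()), int(high_mask[i].sum())
        if nl:
            y[i, low_mask[i]] = np.maximum(
                rng.gamma(shape=shape[i], scale=1.0 / rate[i], size=nl), _MIN_POSITIVE
            )
        if nh:
            y[i, high_mask[i]] = np.maximum(
                rng.normal(mean[i], sd[i], size=nh), _MIN_POSITIVE
            )

    # back-convert to integer counts at a nominal library size of 1e6
    counts = np.rint(np.exp2(y) - 1.0).astype(np.int64)
    counts[(states > 0) & (counts == 0)] = 1  # keep the zero pattern of the truth
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = [cell_names[j] for j in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(f"back-conversion produced empty cells: {', '.join(bad)}")

    counts_df = pd.DataFrame(counts, index=gene_names, columns=cell_names)
    truth = TruthTables(
        states=pd.DataFrame(states, index=gene_names, columns=cell_names),
        cell_group=pd.Series(cell_group, index=cell_names, name="group"),
        network_role=pd.Series(network_role, index=cell_names, name="network_role"),
        mature_assoc_genes=roles["mature_assoc"],
        immature_assoc_genes=roles["immature_assoc"],
        anchors=(mp.mature_marker, mp.immature_marker) if mp else None,
    )
    return counts_df, truth


def generate_null(spec: SyntheticSpec) -> tuple[pd.DataFrame, TruthTables]:
    """As :func:`generate` but with no planted contrast or topology.

    Anchor markers still define mature/immature groups (so group-based scans
    can run), but every other gene is exchangeable between the groups; used
    for type-I-error and permutation checks.
    """
    mp = spec.marker_plan or MarkerPlan()
    null_plan = replace(mp, n_mature_assoc=0, n_immature_assoc=0)
    return generate(replace(spec, marker_plan=null_plan, network_plan=None))


def network_study_spec(
    n_background_genes: int = 100,
    n_other_cells: int = 140,
    seed: int = 0,
    network_plan: NetworkPlan = NetworkPlan(),
) -> SyntheticSpec:
    """Study conditions for the planted-topology contrast.

    Background activity is kept sparse (rho = 0.05, dropout 0.7) so the
    planted star / clique structure dominates each planted cell's active gene
    set; the unlabelled cells enlarge the population so that a uniquely
    coactive pair (prevalence 1/n_cells) survives even the tightest 0.5%
    prevalence cutoff.
    """
    n_planted = (
        2
        + network_plan.n_shared_genes
        + network_plan.n_star_cells
        + network_plan.n_dense_cells * network_plan.n_private_per_dense
    )
    return SyntheticSpec(
        n_genes=n_planted + n_background_genes,
        n_cells=network_plan.n_star_cells + network_plan.n_dense_cells + n_other_cells,
        zero_prob=0.7,
        rho=0.05,
        marker_plan=MarkerPlan(
            n_mature_cells=network_plan.n_star_cells,
            n_immature_cells=network_plan.n_dense_cells,
            n_mature_assoc=0,
            n_immature_assoc=0,
        ),
        network_plan=network_plan,
        seed=seed,
    )
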