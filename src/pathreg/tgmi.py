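"""Triple-gene mutual interaction (TGMI) engine.

TGMI scores every (TF, pathway-gene-pair) triple block with conditional mutual
information (CMI) computed on discretized expression, attaches permutation
p-values to each CMI, and keeps the blocks whose interactions are jointly
significant.  Significant blocks are collapsed into a bipartite TF -> gene
network, and TFs are ranked by connectivity — the number of distinct pathway
genes they are linked to.

For a triple block (t, g_i, g_j) with g_i < g_j the three statistics are::

    cmi_t_i = I(t; g_i | g_j)      TF/gene interaction given the partner gene
    cmi_t_j = I(t; g_j | g_i)
    cmi_ij  = I(g_i; g_j | t)      co-expression of the pair given the TF

and the mutual interaction measure (MIM) is their arithmetic mean; MIM is an
effect-size summary used for edge weights and tie-breaks, never for
significance.  Significance of each CMI is assessed by permuting the sample
order of its first variable (an exact exchangeable null for independence) and
p = (1 + #{null >= observed}) / (R + 1).

The default joint-significance rule ("both-tf") requires both TF-involving
CMI p-values to be <= alpha.  The stricter "all-three" rule additionally
requires the pair CMI I(g_i; g_j | t) to be significant; under a faithful
TF -> (g_i, g_j) fan-out the two genes are conditionally independent given
the TF, so that statistic carries no excess over its permutation null and the
strict rule empirically discards exactly the blocks the method is built to
find (see docs/methods.md).  Both rules are exposed via ``TGMIParams``.

Determinism: each triplet draws its permutations from a seed derived from
(master seed, tf_id, gene_i, gene_j), so results are invariant to the order
in which triplets are evaluated.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .information import (
    BinnedVector,
    conditional_mutual_information,
    default_n_bins,
    discretize_equal_frequency,
)
from .io import ExpressionMatrix
from .ranking import build_ranking

__all__ = [
    "TGMIParams",
    "TripletScore",
    "BipartiteNetwork",
    "TGMI",
    "TGMIResults",
    "score_triplet",
    "permutation_pvalue",
    "run_tgmi",
    "rank_regulators",
    "significant_mask",
    "build_network",
]

logger = logging.getLogger(__name__)

#: numerical slack when comparing null statistics against the observed one,
#: so ties between algebraically equal floats are counted as ties
_TIE_TOL = 1e-12

SIGNIFICANCE_RULES = ("both-tf", "all-three")


@dataclass(frozen=True)
class TGMIParams:
    """Estimation settings for a TGMI run.

    The method itself has no tuning parameters; these fix the estimator
    (bin count), the resampling effort and the significance level.
    """

    alpha: float = 0.05
    n_permutations: int = 1000
    n_bins: int | None = None  # None -> Sturges clamped to [2, 8]
    seed: int = 0
    top_k: int = 50
    significance_rule: str = "both-tf"
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 19:
            raise ValueError("need at least 19 permutations")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.significance_rule not in SIGNIFICANCE_RULES:
            raise ValueError(f"significance_rule must be one of {SIGNIFICANCE_RULES}")
        if self.n_bins is not None and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass(frozen=True)
class TripletScore:
    """Statistics for one (TF, gene_i, gene_j) block with gene_i < gene_j."""

    tf_id: str
    gene_i: str
    gene_j: str
    cmi_t_i: float
    cmi_t_j: float
    cmi_ij: float
    mim: float
    p_t_i: float
    p_t_j: float
    p_ij: float
    significant: bool


@dataclass
class BipartiteNetwork:
    """TF -> pathway-gene edges distilled from significant triplets.

    ``edges`` columns: tf_id, gene_id, weight (mean MIM over supporting
    triplets), support (number of significant triplets containing the pair).
    """

    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["tf_id", "gene_id", "weight", "support"]
        )
    )

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# permutation machinery

def _triplet_seed_sequence(seed: int, tf_id: str, gene_i: str, gene_j: str):
    """Per-triplet seed derived from the master seed and the triplet identity."""
    digest = hashlib.blake2b(
        f"{tf_id}\x1f{gene_i}\x1f{gene_j}".encode(), digest_size=8
    ).digest()
    return np.random.SeedSequence([int(seed), int.from_bytes(digest, "big")])


def _permutation_block(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    """R independent permutations of range(n), one per row."""
    idx = np.tile(np.arange(n), (n_perm, 1))
    return rng.permuted(idx, axis=1)


def _klogk_table(n: int) -> np.ndarray:
    k = np.arange(n + 1, dtype=float)
    table = np.zeros(n + 1)
    table[1:] = k[1:] * np.log(k[1:])
    return table


def _cmi_rows(
    a_rows: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    n_a: int,
    n_b: int,
    n_c: int,
    table: np.ndarray,
) -> np.ndarray:
    """Plug-in I(A;B|C) for each row of ``a_rows`` against fixed ``b``, ``c``.

    Uses H(AC) + H(BC) - H(C) - H(ABC) with entropies expressed through a
    precomputed k*log(k) lookup; the log(n) terms cancel.
    """
    n_rows, n = a_rows.shape
    code = (a_rows * n_b + b[None, :]) * n_c + c[None, :]
    n_states = n_a * n_b * n_c
    flat = (code + (np.arange(n_rows) * n_states)[:, None]).ravel()
    counts = np.bincount(flat, minlength=n_rows * n_states)
    counts = counts.reshape(n_rows, n_a, n_b, n_c)
    s_abc = table[counts].sum(axis=(1, 2, 3))
    counts_ac = counts.sum(axis=2)
    s_ac = table[counts_ac].sum(axis=(1, 2))
    counts_bc = counts.sum(axis=1)
    s_bc = table[counts_bc].sum(axis=(1, 2))
    s_c = table[counts_ac.sum(axis=1)].sum(axis=1)
    cmi = (s_abc + s_c - s_ac - s_bc) / n
    np.clip(cmi, 0.0, None, out=cmi)
    cmi[np.abs(cmi) < 1e-15] = 0.0
    return cmi


def _empirical_pvalue(null: np.ndarray, observed: float) -> float:
    r = null.size
    return float((1 + np.count_nonzero(null >= observed - _TIE_TOL)) / (r + 1))


def permutation_pvalue(stat_fn, a, b, c, n_permutations: int, seed) -> float:
    """Permutation p-value for ``stat_fn(a, b, c)`` under shuffles of ``a``.

    Only the sample order of the first argument is permuted, giving an exact
    exchangeable null for independence of ``a`` from ``(b, c)``; the p-value
    is (1 + #{null >= observed}) / (R + 1), so its minimum is 1/(R+1).
    Deterministic given ``seed`` (an int or a ``SeedSequence``).
    """
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations")
    a = np.asarray(a)
    rng = np.random.default_rng(seed)
    perms = _permutation_block(rng, n_permutations, a.shape[0])
    observed = float(stat_fn(a, b, c))
    null = np.array([float(stat_fn(a[p], b, c)) for p in perms])
    return _empirical_pvalue(null, observed)


# ---------------------------------------------------------------------------
# triplet scoring

def _bin_vector(x, n_bins: int | None) -> BinnedVector:
    x = np.asarray(x, dtype=float).ravel()
    bins = n_bins if n_bins is not None else default_n_bins(x.size)
    return discretize_equal_frequency(x, bins)


def score_triplet(t, gi, gj, params: TGMIParams | None = None):
    """CMI statistics for one triple block (no significance assessment).

    Returns ``(cmi_t_i, cmi_t_j, cmi_ij, mim)`` where MIM is the arithmetic
    mean of the three CMIs.  Constant vectors collapse to a single bin so the
    CMIs involving them are exactly zero.
    """
    params = params or TGMIParams()
    t = np.asarray(t, dtype=float).ravel()
    if t.size < 8:
        raise ValueError("need at least 8 samples per triplet")
    bt, bi, bj = (_bin_vector(v, params.n_bins) for v in (t, gi, gj))
    if 1 in (bt.n_bins_used, bi.n_bins_used, bj.n_bins_used):
        logger.info("constant vector in triplet; degenerate single-bin encoding used")
    cmi_t_i = conditional_mutual_information(bt, bi, bj)
    cmi_t_j = conditional_mutual_information(bt, bj, bi)
    cmi_ij = conditional_mutual_information(bi, bj, bt)
    mim = (cmi_t_i + cmi_t_j + cmi_ij) / 3.0
    return cmi_t_i, cmi_t_j, cmi_ij, mim


def _triplet_stats_and_pvalues(
    bt: BinnedVector,
    bi: BinnedVector,
    bj: BinnedVector,
    n_permutations: int,
    seed_seq,
    table: np.ndarray,
):
    """Observed CMIs and permutation p-values for one triple block.

    The TF labels are permuted for the two TF-involving CMIs and gene_i's
    labels for the pair CMI.  Each of the three tests draws its own
    independent block of permutations: with a shared block, two nearly equal
    statistics (as arise for tightly co-expressed gene pairs) would get
    identical p-values, and a joint significance rule would collapse to a
    single marginal test.
    """
    lt, li, lj = bt.labels, bi.labels, bj.labels
    n_t, n_i, n_j = bt.n_bins_used, bi.n_bins_used, bj.n_bins_used
    rng = np.random.default_rng(seed_seq)
    perms_ti = _permutation_block(rng, n_permutations, lt.size)
    perms_tj = _permutation_block(rng, n_permutations, lt.size)
    perms_i = _permutation_block(rng, n_permutations, lt.size)

    obs_ti = _cmi_rows(lt[None, :], li, lj, n_t, n_i, n_j, table)[0]
    obs_tj = _cmi_rows(lt[None, :], lj, li, n_t, n_j, n_i, table)[0]
    obs_ij = _cmi_rows(li[None, :], lj, lt, n_i, n_j, n_t, table)[0]

    null_ti = _cmi_rows(lt[perms_ti], li, lj, n_t, n_i, n_j, table)
    null_tj = _cmi_rows(lt[perms_tj], lj, li, n_t, n_j, n_i, table)
    null_ij = _cmi_rows(li[perms_i], lj, lt, n_i, n_j, n_t, table)

    pvals = (
        _empirical_pvalue(null_ti, obs_ti),
        _empirical_pvalue(null_tj, obs_tj),
        _empirical_pvalue(null_ij, obs_ij),
    )
    return (float(obs_ti), float(obs_tj), float(obs_ij)), pvals


def triplet_pvalues(t, gi, gj, params: TGMIParams, seed=None):
    """Observed CMIs and their permutation p-values for raw expression vectors.

    ``seed`` defaults to ``params.seed``; pass a derived seed to reproduce a
    specific triplet from a full run.
    """
    t = np.asarray(t, dtype=float).ravel()
    bt, bi, bj = (_bin_vector(v, params.n_bins) for v in (t, gi, gj))
    table = _klogk_table(t.size)
    seed_seq = params.seed if seed is None else seed
    return _triplet_stats_and_pvalues(
        bt, bi, bj, params.n_permutations, seed_seq, table
    )


# ---------------------------------------------------------------------------
# full run

def significant_mask(
    triplets: pd.DataFrame, alpha: float, rule: str = "both-tf", bh: bool = False
) -> np.ndarray:
    """Joint-significance flags for a triplet table at level ``alpha``.

    ``rule="all-three"`` requires all three p-values <= alpha; ``"both-tf"``
    requires only the TF-involving pair.  With ``bh=True`` each p-value family
    is Benjamini-Hochberg adjusted across triplets first.
    """
    if rule not in SIGNIFICANCE_RULES:
        raise ValueError(f"significance_rule must be one of {SIGNIFICANCE_RULES}")
    cols = ["p_t_i", "p_t_j"] + (["p_ij"] if rule == "all-three" else [])
    pvals = triplets.loc[:, cols].to_numpy(dtype=float)
    if bh and len(triplets):
        from statsmodels.stats.multitest import multipletests

        adjusted = np.column_stack(
            [multipletests(pvals[:, k], method="fdr_bh")[1] for k in range(pvals.shape[1])]
        )
        pvals = adjusted
    if len(triplets) == 0:
        return np.zeros(0, dtype=bool)
    return (pvals <= alpha).all(axis=1)


def build_network(triplets: pd.DataFrame) -> BipartiteNetwork:
    """Collapse significant triplets into weighted TF -> gene edges."""
    sig = triplets.loc[triplets["significant"]]
    if sig.empty:
        return BipartiteNetwork()
    halves = pd.concat(
        [
            sig.loc[:, ["tf_id", "gene_i", "mim"]].rename(columns={"gene_i": "gene_id"}),
            sig.loc[:, ["tf_id", "gene_j", "mim"]].rename(columns={"gene_j": "gene_id"}),
        ],
        ignore_index=True,
    )
    grouped = halves.groupby(["tf_id", "gene_id"], as_index=False).agg(
        weight=("mim", "mean"), support=("mim", "size")
    )
    grouped = grouped.sort_values(["tf_id", "gene_id"], kind="mergesort").reset_index(
        drop=True
    )
    return BipartiteNetwork(grouped)


def rank_regulators(triplets: pd.DataFrame, top_k: int) -> pd.DataFrame:
    """Rank TFs by connectivity over their significant triplets only."""
    sig = triplets.loc[triplets["significant"]]
    if sig.empty:
        return build_ranking(pd.DataFrame(columns=["tf_id", "connectivity"]), top_k, "tgmi")
    records = []
    for tf_id, block in sig.groupby("tf_id"):
        genes = set(block["gene_i"]) | set(block["gene_j"])
        records.append(
            {
                "tf_id": tf_id,
                "connectivity": len(genes),
                "n_triplets": len(block),
                "strength": float(block["mim"].mean()),
            }
        )
    return build_ranking(pd.DataFrame.from_records(records), top_k, "tgmi")


def _as_expression(matrix) -> ExpressionMatrix:
    if isinstance(matrix, ExpressionMatrix):
        return matrix
    if isinstance(matrix, pd.DataFrame):
        return ExpressionMatrix.from_dataframe(matrix)
    raise TypeError("expected an ExpressionMatrix or a genes x samples DataFrame")


class TGMI:
    """Triple-gene mutual interaction model over a TF block and a pathway block.

    Parameters
    ----------
    tf_matrix, pathway_matrix
        Genes x samples blocks (``ExpressionMatrix`` or ``DataFrame``) sharing
        the same sample axis; typically produced by
        :func:`pathreg.io.assemble_design`.
    """

    def __init__(self, tf_matrix, pathway_matrix):
        self.tf_matrix = _as_expression(tf_matrix)
        self.pathway_matrix = _as_expression(pathway_matrix)
        if self.tf_matrix.sample_ids != self.pathway_matrix.sample_ids:
            raise ValueError("TF and pathway matrices must share the sample axis")
        if self.pathway_matrix.n_genes < 2:
            raise ValueError("need at least 2 pathway genes")
        if self.tf_matrix.n_genes < 1:
            raise ValueError("need at least 1 TF")

    @classmethod
    def from_expression(cls, expr, spec) -> "TGMI":
        from .io import assemble_design

        tf_m, path_m, _ = assemble_design(expr, spec)
        return cls(tf_m, path_m)

    def fit(self, params: TGMIParams | None = None, **overrides) -> "TGMIResults":
        """Score every TF x gene-pair triple block and assemble the results."""
        params = params or TGMIParams()
        if overrides:
            params = replace(params, **overrides)
        n = self.tf_matrix.n_samples
        if n < 8:
            raise ValueError("need at least 8 samples")
        n_bins = params.n_bins if params.n_bins is not None else default_n_bins(n)
        table = _klogk_table(n)

        tf_ids = self.tf_matrix.gene_ids
        gene_ids = sorted(self.pathway_matrix.gene_ids)
        tf_binned = {
            g: discretize_equal_frequency(self.tf_matrix.row(g), n_bins) for g in tf_ids
        }
        gene_binned = {
            g: discretize_equal_frequency(self.pathway_matrix.row(g), n_bins)
            for g in gene_ids
        }
        pairs = list(combinations(gene_ids, 2))

        rows = []
        for tf_id in tf_ids:
            bt = tf_binned[tf_id]
            for gene_i, gene_j in pairs:
                seed_seq = _triplet_seed_sequence(params.seed, tf_id, gene_i, gene_j)
                (cmi_ti, cmi_tj, cmi_ij), (p_ti, p_tj, p_ij) = (
                    _triplet_stats_and_pvalues(
                        bt,
                        gene_binned[gene_i],
                        gene_binned[gene_j],
                        params.n_permutations,
                        seed_seq,
                        table,
                    )
                )
                rows.append(
                    (
                        tf_id,
                        gene_i,
                        gene_j,
                        cmi_ti,
                        cmi_tj,
                        cmi_ij,
                        (cmi_ti + cmi_tj + cmi_ij) / 3.0,
                        p_ti,
                        p_tj,
                        p_ij,
                    )
                )
        triplets = pd.DataFrame(
            rows,
            columns=[
                "tf_id",
                "gene_i",
                "gene_j",
                "cmi_t_i",
                "cmi_t_j",
                "cmi_ij",
                "mim",
                "p_t_i",
                "p_t_j",
                "p_ij",
            ],
        )
        triplets["significant"] = significant_mask(
            triplets, params.alpha, params.significance_rule, params.bh_correction
        )
        logger.info(
            "TGMI: %d triplets scored, %d significant",
            len(triplets),
            int(triplets["significant"].sum()),
        )
        network = build_network(triplets)
        ranking = rank_regulators(triplets, params.top_k)
        return TGMIResults(self, params, triplets, network, ranking)


@dataclass
class TGMIResults:
    """Fitted TGMI state: the triplet table, the network and the TF ranking."""

    model: TGMI
    params: TGMIParams
    triplets: pd.DataFrame
    network: BipartiteNetwork
    ranking: pd.DataFrame

    def at_alpha(self, alpha: float) -> "TGMIResults":
        """Re-threshold the stored p-values at a different significance level."""
        params = replace(self.params, alpha=alpha)
        triplets = self.triplets.copy()
        triplets["significant"] = significant_mask(
            triplets, alpha, params.significance_rule, params.bh_correction
        )
        return TGMIResults(
            self.model,
            params,
            triplets,
            build_network(triplets),
            rank_regulators(triplets, params.top_k),
        )

    def summary(self) -> str:
        lines = [
            "Triple-gene mutual interaction (TGMI)",
            f"  TFs: {self.model.tf_matrix.n_genes}  pathway genes: "
            f"{self.model.pathway_matrix.n_genes}  samples: "
            f"{self.model.tf_matrix.n_samples}",
            f"  triplets scored: {len(self.triplets)}  significant: "
            f"{int(self.triplets['significant'].sum())} "
            f"(alpha={self.params.alpha}, rule={self.params.significance_rule}, "
            f"R={self.params.n_permutations})",
            f"  network edges: {self.network.n_edges}",
            "",
            "Top regulators by connectivity:",
        ]
        head = self.ranking.head(10)
        if head.empty:
            lines.append("  (no significant triplets)")
        else:
            lines.append(
                head.to_string(
                    index=False, float_format=lambda v: f"{v:.4f}"
                ).replace("\n", "\n  ")
            )
        return "\n".join(lines)


def run_tgmi(tf_matrix, pathway_matrix, params: TGMIParams | None = None):
    """Functional wrapper: score all triple blocks and return
    ``(triplet table, network, ranking)``."""
    results = TGMI(tf_matrix, pathway_matrix).fit(params)
    return results.triplets, results.network, results.ranking
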