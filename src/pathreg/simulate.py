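"""Synthetic expression compendia with planted TF -> pathway-gene regulation.

The generator emulates the structure both engines exploit in real compendia:

* TFs drawn from a block-structured correlated Gaussian (blocks of
  ``block_size`` with pairwise correlation ``rho``) — multicollinearity among
  candidate regulators;
* a subset of TFs are true regulators, each driving ``targets_per_regulator``
  pathway genes through a linear, quadratic or tanh link with effect size
  ``beta`` plus Gaussian noise — so co-regulated pathway genes are tightly
  co-expressed and share a common driver;
* targets are assigned round-robin, so consecutive regulators share pathway
  genes and every regulator appears in triple blocks with two of its targets;
* non-targeted pathway genes are pure noise.

Everything is determined by ``seed``.  The ``easy`` preset is the reference
benchmark condition (200 samples, 300 TFs, 20 pathway genes, 8 regulators
with 3 targets each, beta = 1, noise sd = 0.5, rho = 0.2); ``collinear``
raises rho to 0.8 and ``nonlinear`` swaps the link for a symmetric quadratic,
which has zero linear correlation with the TF and therefore handicaps
correlation-based detection while leaving mutual information intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import ExpressionMatrix

__all__ = ["SimParams", "SyntheticTruth", "generate_dataset", "preset", "PRESETS"]

_LINKS = {
    "identity": lambda x: x,
    "quadratic": lambda x: x**2,
    "tanh": np.tanh,
}


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults mirror the ``easy`` preset."""

    n_samples: int = 200
    n_tfs: int = 300
    n_pathway_genes: int = 20
    n_true_regulators: int = 8
    targets_per_regulator: int = 3
    effect_size: float = 1.0
    link: str = "identity"
    noise_sd: float = 0.5
    tf_block_corr: float = 0.2
    block_size: int = 10
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.n_true_regulators > self.n_tfs:
            raise ValueError("more true regulators than TFs")
        if self.targets_per_regulator < 2:
            raise ValueError(
                "each regulator needs >= 2 targets to appear in a triple block"
            )
        if self.targets_per_regulator > self.n_pathway_genes:
            raise ValueError("more targets per regulator than pathway genes")
        if not 0.0 <= self.tf_block_corr < 1.0:
            raise ValueError("tf_block_corr must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.link not in _LINKS:
            raise ValueError(f"unknown link {self.link!r}; choose from {sorted(_LINKS)}")


@dataclass
class SyntheticTruth:
    """Planted ground truth: regulator IDs and the TF -> gene adjacency."""

    regulator_ids: list
    adjacency: list  # (tf_id, gene_id, beta) triples
    params: SimParams = field(default_factory=SimParams)

    def to_dict(self) -> dict:
        return {
            "regulator_ids": list(self.regulator_ids),
            "adjacency": [list(edge) for edge in self.adjacency],
            "params": {
                key: getattr(self.params, key) for key in self.params.__dataclass_fields__
            },
        }


PRESETS = {
    "easy": SimParams(),
    "collinear": replace(SimParams(), tf_block_corr=0.8),
    "nonlinear": replace(SimParams(), link="quadratic"),
}


def preset(name: str) -> SimParams:
    """A named benchmark condition: ``easy``, ``collinear`` or ``nonlinear``."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None


def generate_dataset(params: SimParams) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one synthetic compendium; fully determined by ``params.seed``.

    The returned matrix stacks TF rows (``TF0001``...) above pathway rows
    (``PG0001``...), genes x samples.
    """
    rng = np.random.default_rng(params.seed)
    n, p = params.n_samples, params.n_tfs
    link = _LINKS[params.link]

    # block-equicorrelated standard-normal TFs:
    # x = sqrt(rho) * z_block + sqrt(1 - rho) * e
    rho = params.tf_block_corr
    tf_values = np.empty((p, n))
    start = 0
    while start < p:
        size = min(params.block_size, p - start)
        shared = rng.standard_normal(n)
        noise = rng.standard_normal((size, n))
        tf_values[start : start + size] = (
            np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        )
        start += size

    tf_ids = [f"TF{i + 1:04d}" for i in range(p)]
    gene_ids = [f"PG{i + 1:04d}" for i in range(params.n_pathway_genes)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    regulators = sorted(
        rng.choice(p, size=params.n_true_regulators, replace=False).tolist()
    )
    # round-robin target assignment: consecutive regulators share pathway genes
    # once the assignments wrap around the pathway-gene axis
    adjacency = []
    targets_of: dict[int, list[int]] = {}
    cursor = 0
    for reg in regulators:
        targets = [
            (cursor + offset) % params.n_pathway_genes
            for offset in range(params.targets_per_regulator)
        ]
        cursor = (cursor + params.targets_per_regulator) % params.n_pathway_genes
        targets_of[reg] = targets
        adjacency.extend(
            (tf_ids[reg], gene_ids[g], params.effect_size) for g in targets
        )

    noise = rng.standard_normal((params.n_pathway_genes, n)) * params.noise_sd
    pathway_values = noise.copy()
    for reg, targets in targets_of.items():
        signal = params.effect_size * link(tf_values[reg])
        for g in targets:
            pathway_values[g] += signal

    matrix = ExpressionMatrix(
        tf_ids + gene_ids,
        sample_ids,
        np.vstack([tf_values, pathway_values]),
    )
    truth = SyntheticTruth(
        regulator_ids=[tf_ids[r] for r in regulators],
        adjacency=adjacency,
        params=params,
    )
    return matrix, truth
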