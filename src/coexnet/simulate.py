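"""Latent-factor simulator for modular expression data.

Each planted module m is driven by one latent factor per sample,
``u_ms ~ N(0, 1)``; member gene i observes ``x_is = l_i * u_ms + eps`` with
loading ``l_i`` drawn uniformly from a configured range and Gaussian noise.
This is the generative form whose correlation structure a weighted
coexpression analysis assumes (block-correlated modules with a natural
eigengene ground truth), so recovery of the planted labels is a meaningful
end-to-end check.

Condition-specific perturbations are applied to the case (HS) samples only,
keeping the control (CTRL) condition as the shared reference network:

``gain``
    member loadings multiplied by ``gain_factor`` in HS samples, raising
    within-module correlation and intramodular connectivity there;
``loss``
    loadings divided by ``gain_factor`` in HS samples;
``destroy``
    HS values replaced by independent noise (the module exists only in CTRL);
``shift``
    every member gene's HS mean raised by ``de_effect`` log2 units, making
    the module eigengene track the group indicator (a trait-linked module);
``none``
    the two conditions are exchangeable.

Differentially expressed genes get a ``+/- de_effect`` (log2 units) mean
shift in all HS samples.  A baseline of 8 is added throughout so values
resemble log2 microarray intensities.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_dataset", "write_fixture"]

BASELINE_LOG2 = 8.0

#: default planted design: six modules plus uncorrelated background genes,
#: sized so the full pipeline runs in minutes on one CPU
DEFAULT_MODULE_SIZES = (300, 250, 200, 150, 100, 80)
DEFAULT_N_BACKGROUND = 1000


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; all randomness flows from ``seed``."""

    module_sizes: tuple[int, ...] = DEFAULT_MODULE_SIZES
    n_background: int = DEFAULT_N_BACKGROUND
    n_samples_per_group: int = 8  # per group per time point
    groups: tuple[str, ...] = ("CTRL", "HS")
    timepoints: tuple[str, ...] = ("P12", "P30", "P60", "P120")
    loading_range: tuple[float, float] = (0.4, 0.9)
    noise_sd: float = 1.0
    perturbations: dict[str, str] = field(default_factory=dict)  # module label -> kind
    gain_factor: float = 2.0
    de_genes: int = 0
    de_effect: float = 1.0
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return int(sum(self.module_sizes)) + int(self.n_background)

    def module_labels(self) -> list[str]:
        return [f"M{i + 1}" for i in range(len(self.module_sizes))]

    def validate(self) -> None:
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("every module must have at least 2 genes")
        if self.n_background < 0:
            raise ValueError("n_background must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.gain_factor <= 1:
            raise ValueError("gain_factor must exceed 1")
        if not (0 <= self.loading_range[0] <= self.loading_range[1]):
            raise ValueError("loading_range must be an ordered pair of non-negative floats")
        if self.de_genes > self.n_background:
            raise ValueError("de_genes must not exceed n_background (DE genes are planted in the background)")
        labels = set(self.module_labels())
        for mod, kind in self.perturbations.items():
            if mod not in labels:
                raise ValueError(f"perturbation refers to unknown module {mod!r}")
            if kind not in ("none", "gain", "loss", "destroy", "shift"):
                raise ValueError(f"unknown perturbation kind {kind!r}")


@dataclass
class SyntheticTruth:
    """Planted ground truth: module labels, perturbations, DE genes."""

    module_of_gene: dict[str, str]  # gene id -> module label or "background"
    perturbation_of_module: dict[str, str]
    de_gene_ids: list[str]
    de_direction: dict[str, str]  # gene id -> "up" | "down"

    def to_frame(self) -> pd.DataFrame:
        genes = list(self.module_of_gene)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "module": [self.module_of_gene[g] for g in genes],
                "perturbation": [
                    self.perturbation_of_module.get(self.module_of_gene[g], "none") for g in genes
                ],
                "de_direction": [self.de_direction.get(g, "") for g in genes],
            }
        )


def _sample_table(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group in config.groups:
        for tp in config.timepoints:
            for i in range(config.n_samples_per_group):
                rows.append(
                    {
                        "sample_id": f"{group}_{tp}_s{i + 1}",
                        "group": group,
                        "timepoint": tp,
                        "sex": "M" if rng.random() < 0.5 else "F",
                    }
                )
    return pd.DataFrame(rows)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (expression, samples, truth) for a planted-module design.

    Returns the expression matrix as a genes x samples DataFrame on the log2
    intensity scale, the sample table, and the planted truth.  Fixing the
    seed makes the output byte-identical across calls.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _sample_table(config, rng)
    sample_ids = samples["sample_id"].tolist()
    n_samples = len(sample_ids)
    is_hs = (samples["group"] == "HS").to_numpy()

    module_labels = config.module_labels()
    gene_ids: list[str] = []
    module_of_gene: dict[str, str] = {}
    for label, size in zip(module_labels, config.module_sizes):
        for j in range(size):
            gid = f"{label}_g{j + 1:04d}"
            gene_ids.append(gid)
            module_of_gene[gid] = label
    for j in range(config.n_background):
        gid = f"BG_g{j + 1:05d}"
        gene_ids.append(gid)
        module_of_gene[gid] = "background"

    values = np.empty((len(gene_ids), n_samples))
    lo, hi = config.loading_range
    row = 0
    for label, size in zip(module_labels, config.module_sizes):
        kind = config.perturbations.get(label, "none")
        u = rng.standard_normal(n_samples)
        loadings = rng.uniform(lo, hi, size=size)
        eff = np.tile(loadings[:, None], (1, n_samples))
        if kind == "gain":
            eff[:, is_hs] *= config.gain_factor
        elif kind == "loss":
            eff[:, is_hs] /= config.gain_factor
        block = eff * u[None, :] + rng.standard_normal((size, n_samples)) * config.noise_sd
        if kind == "destroy":
            block[:, is_hs] = rng.standard_normal((size, int(is_hs.sum()))) * config.noise_sd
        elif kind == "shift":
            block[:, is_hs] += config.de_effect
        values[row : row + size] = block
        row += size
    if config.n_background:
        values[row:] = rng.standard_normal((config.n_background, n_samples)) * config.noise_sd

    de_gene_ids: list[str] = []
    de_direction: dict[str, str] = {}
    if config.de_genes:
        bg_ids = [g for g in gene_ids if module_of_gene[g] == "background"]
        chosen = rng.choice(len(bg_ids), size=config.de_genes, replace=False)
        for idx in np.sort(chosen):
            gid = bg_ids[int(idx)]
            direction = "up" if rng.random() < 0.5 else "down"
            shift = config.de_effect if direction == "up" else -config.de_effect
            values[gene_ids.index(gid)][is_hs] += shift
            de_gene_ids.append(gid)
            de_direction[gid] = direction

    values += BASELINE_LOG2
    expr = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    expr.attrs["stage"] = "normalized"
    truth = SyntheticTruth(
        module_of_gene=module_of_gene,
        perturbation_of_module={m: config.perturbations.get(m, "none") for m in module_labels},
        de_gene_ids=de_gene_ids,
        de_direction=de_direction,
    )
    return expr, samples, truth


def write_fixture(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    truth: SyntheticTruth,
    directory: str | os.PathLike,
) -> dict[str, str]:
    """Write expression / sample / truth tables as TSV; returns the paths.

    The expression TSV has gene rows and a header row of sample ids, so the
    file round-trips losslessly through :func:`coexnet.io.read_expression`.
    """
    if expr.shape[0] == 0:
        raise ValueError("refusing to write an empty expression matrix")
    os.makedirs(directory, exist_ok=True)
    paths = {
        "expression": os.path.join(directory, "expression.tsv"),
        "samples": os.path.join(directory, "samples.tsv"),
        "truth": os.path.join(directory, "truth.tsv"),
    }
    expr.to_csv(paths["expression"], sep="\t", float_format="%.10g")
    samples.to_csv(paths["samples"], sep="\t", index=False)
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
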