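"""Generate the synthetic study datasets used by the downstream analyses.

Writes three fixtures under results/data/:
  default/   the default planted design (6 modules + background, 64 samples)
  paired/    two 200-gene modules, one destroyed in the HS condition
  de/        2,020 genes with 20 planted mean-shift DE genes, 8 vs 8 samples
"""

import argparse

from coexnet.simulate import SyntheticConfig, generate_dataset, write_fixture


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", default="results/data")
    args = parser.parse_args()

    configs = {
        "default": SyntheticConfig(seed=args.seed),
        "paired": SyntheticConfig(
            module_sizes=(200, 200), n_background=600, loading_range=(0.5, 0.9),
            noise_sd=1.0, perturbations={"M2": "destroy"}, seed=args.seed + 6,
        ),
        "de": SyntheticConfig(
            module_sizes=(), n_background=2020, de_genes=20, de_effect=3.0,
            timepoints=("P12",), n_samples_per_group=8, seed=args.seed + 4,
        ),
    }
    for name, config in configs.items():
        expr, samples, truth = generate_dataset(config)
        paths = write_fixture(expr, samples, truth, f"{args.out}/{name}")
        print(
            f"{name}: {expr.shape[0]} genes x {expr.shape[1]} samples "
            f"({len(truth.de_gene_ids)} DE genes planted) -> {paths['expression']}"
        )


if __name__ == "__main__":
    main()
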