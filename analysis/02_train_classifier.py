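#!/usr/bin/env python
"""Train the continuous caste classifier on control queens and workers.

Filters low-count genes, normalizes to log2-CPM, standardizes per gene, runs
recursive feature elimination (threefold CV repeated 20x per iteration) and
keeps the minimum-error model. Writes the RFE trace, the selected gene set
and the serialized model under results/model/.
"""

from pathlib import Path

from castesvm.config import stage_seed
from castesvm.preprocess import read_counts, read_gene_set, read_samples, write_gene_set
from castesvm.pipeline import train_caste_classifier

SEED = 1
DATA = Path("results/data")
OUT = Path("results/model")


def main():
    counts = read_counts(DATA / "counts.tsv")
    samples = read_samples(DATA / "samples.tsv")
    trained = train_caste_classifier(counts, samples,
                                     seed=stage_seed(SEED, "rfe"))
    OUT.mkdir(parents=True, exist_ok=True)
    trained.trace.to_frame().to_csv(OUT / "rfe_trace.tsv", sep="\t", index=False)
    write_gene_set(trained.selected.genes, OUT / "selected_genes.txt")
    write_gene_set(trained.universe, OUT / "universe_genes.txt")
    (OUT / "model.json").write_text(trained.selected.model.to_json() + "\n")
    trained.training_estimates.rename_axis("sample_id").reset_index().to_csv(
        OUT / "training_estimates.tsv", sep="\t", index=False)

    planted = set(read_gene_set(DATA / "informative_genes.txt"))
    planted &= set(trained.universe)
    rec = len(set(trained.selected.genes) & planted) / len(planted)
    print(f"all-genes CV error (MSE): {trained.all_genes_cv_error:.4f} "
          f"(RMSE {trained.all_genes_cv_error ** 0.5:.3f})")
    print(f"selected model: {len(trained.selected.genes)} genes, "
          f"CV error {trained.selected.cv_error:.4f} "
          f"(RMSE {trained.selected.cv_error ** 0.5:.3f})")
    print(f"planted caste genes recovered: {100 * rec:.0f}%")
    print(f"artifacts -> {OUT}")


if __name__ == "__main__":
    main()
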