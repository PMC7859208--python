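#!/usr/bin/env python
"""Link classifier estimates of queen-removal individuals to phenotype.

Fits the logistic phenotypic-queenness model on control castes, then
regresses expression-based caste estimates on queenness, ovarian
development, dominance and age, and on age-residualized phenotypes. Writes
results/phenotypes/.
"""

from pathlib import Path

import pandas as pd

from castesvm.preprocess import read_samples
from castesvm.pipeline import (ClassificationReport, fit_phenotype_models,
                               phenotype_queenness)

DATA = Path("results/data")
CLS = Path("results/classification")
OUT = Path("results/phenotypes")


def main():
    samples = phenotype_queenness(read_samples(DATA / "samples.tsv"))
    est = pd.read_csv(CLS / "classification.tsv", sep="\t",
                      dtype={"sample_id": str})
    qr = est.loc[est["group"].str.startswith("qr")]
    report = ClassificationReport.build(qr)
    models = fit_phenotype_models(report, samples)
    OUT.mkdir(parents=True, exist_ok=True)
    samples.to_csv(OUT / "samples_with_queenness.tsv", sep="\t", index=False)
    models.to_csv(OUT / "phenotype_models.tsv", sep="\t", index=False)
    cols = ["model", "slope", "stderr", "p_value", "pearson_r"]
    print(models[cols].round(4).to_string(index=False))
    print(f"artifacts -> {OUT}")


if __name__ == "__main__":
    main()
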