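"""Count-matrix I/O, expression filtering, normalization and standardization.

The pipeline's entry point is a gene x sample matrix of raw read counts plus a
per-sample metadata table. Genes are filtered by a per-group count rule (a gene
is kept iff its counts sum to strictly more than 20 in at least one
experimental group), transformed to log2 counts-per-million, and standardized
per gene using training-set statistics before being fed to the SVR engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "SAMPLE_COLUMNS",
    "read_counts",
    "read_samples",
    "write_counts",
    "write_samples",
    "filter_low_counts",
    "normalize",
    "Scaler",
    "standardize",
    "apply_standardize",
    "read_gene_set",
    "write_gene_set",
]

#: Closed vocabulary of experimental groups: established queens, workers from
#: unmanipulated (queenright) colonies, and workers sampled 3 or 12 days after
#: queen removal.
GROUPS = ("queen", "control_worker", "qr_day3", "qr_day12")

SAMPLE_COLUMNS = ("sample_id", "group", "age", "ovarian_index", "dominance", "queenness")

#: Group count-sum threshold for the expression filter (strict inequality).
FILTER_MIN_COUNTS = 20


def _check_unique(values, what: str) -> None:
    dup = pd.Index(values)[pd.Index(values).duplicated()]
    if len(dup):
        raise ValueError(f"duplicate {what} identifier(s): {sorted(set(dup))[:5]}")


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample count TSV (first column gene ids, header sample ids).

    Raises ``ValueError`` on duplicate identifiers or non-integer counts,
    naming the offending row or column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    for col in df.columns:
        vals = df[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        if numeric.isna().any():
            bad = vals.index[numeric.isna()][0]
            raise ValueError(f"non-numeric count at gene {bad!r}, sample {col!r}")
        if not np.allclose(numeric, np.round(numeric)):
            bad = vals.index[~np.isclose(numeric, np.round(numeric))][0]
            raise ValueError(f"non-integer count at gene {bad!r}, sample {col!r}")
        if (numeric < 0).any():
            bad = vals.index[(numeric < 0)][0]
            raise ValueError(f"negative count at gene {bad!r}, sample {col!r}")
    counts = df.astype(np.int64)
    counts.index.name = "gene"
    return counts


def read_samples(path) -> pd.DataFrame:
    """Read a sample metadata TSV with the canonical column set.

    Columns: sample_id, group, age, ovarian_index, dominance, queenness
    (queenness may be empty; it is fitted downstream).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing column(s): {sorted(missing)}")
    _check_unique(df["sample_id"], "sample")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        row = df.index[df["group"].isin(bad)][0]
        raise ValueError(
            f"unknown group label {df.loc[row, 'group']!r} in row {row} "
            f"(allowed: {list(GROUPS)})"
        )
    return df.set_index("sample_id", drop=False)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_gene_set(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_set(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def _check_samples_cover(counts: pd.DataFrame, samples: pd.DataFrame) -> None:
    missing = set(counts.columns) - set(samples["sample_id"])
    if missing:
        raise ValueError(f"samples table missing count columns: {sorted(missing)[:5]}")


def filter_low_counts(counts: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with a count sum strictly above 20 in at least one group.

    The rule is evaluated over the experimental groups present in ``samples``;
    an entirely absent group triggers a warning, not an error. Gene order and
    the sample column set are preserved.
    """
    _check_samples_cover(counts, samples)
    groups_present = [g for g in GROUPS if (samples["group"] == g).any()]
    if len(groups_present) < len(GROUPS):
        absent = sorted(set(GROUPS) - set(groups_present))
        warnings.warn(f"group(s) with no samples: {absent}; filter evaluated over "
                      f"{groups_present}", stacklevel=2)
    keep = np.zeros(len(counts), dtype=bool)
    for g in groups_present:
        cols = samples.loc[samples["group"] == g, "sample_id"]
        keep |= counts[list(cols)].sum(axis=1).to_numpy() > FILTER_MIN_COUNTS
    return counts.loc[keep]


def normalize(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2 counts-per-million: ``log2(count * 1e6 / depth + pseudocount)``.

    ``depth`` is the sample's column sum. The transform metadata is attached
    under ``.attrs`` (pseudocount and per-sample depth).
    """
    depth = counts.sum(axis=0).astype(float)
    zero = depth.index[depth == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero)}")
    cpm = counts.to_numpy(dtype=float) * 1e6 / depth.to_numpy()
    expr = pd.DataFrame(np.log2(cpm + pseudocount), index=counts.index,
                        columns=counts.columns)
    expr.attrs["pseudocount"] = float(pseudocount)
    expr.attrs["depth"] = {s: float(d) for s, d in depth.items()}
    expr.attrs["transform"] = "log2(count*1e6/depth + pseudocount)"
    return expr


@dataclass
class Scaler:
    """Per-gene training mean/sd, plus genes dropped for zero variance."""

    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.mean.index)

    def to_dict(self) -> dict:
        return {
            "mean": {g: float(v) for g, v in self.mean.items()},
            "sd": {g: float(v) for g, v in self.sd.items()},
            "dropped": list(self.dropped),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(mean=pd.Series(d["mean"], dtype=float),
                   sd=pd.Series(d["sd"], dtype=float),
                   dropped=list(d["dropped"]))


def standardize(train: pd.DataFrame) -> tuple[Scaler, pd.DataFrame]:
    """Center/scale each gene to mean 0, sd 1 across the *training* samples.

    Genes with zero variance in the training data are dropped and recorded in
    the returned :class:`Scaler`. ``train`` is genes x samples.
    """
    if train.shape[1] < 2:
        raise ValueError("standardize requires at least 2 training samples")
    mean = train.mean(axis=1)
    sd = train.std(axis=1, ddof=0)
    dropped = list(sd.index[sd == 0])
    keep = sd.index[sd > 0]
    scaler = Scaler(mean=mean.loc[keep], sd=sd.loc[keep], dropped=dropped)
    z = train.loc[keep].sub(scaler.mean, axis=0).div(scaler.sd, axis=0)
    return scaler, z


def apply_standardize(scaler: Scaler, query: pd.DataFrame) -> pd.DataFrame:
    """Shift/scale ``query`` (genes x samples) by the training statistics."""
    missing = [g for g in scaler.genes if g not in query.index]
    if missing:
        raise ValueError(f"query matrix missing {len(missing)} scaler gene(s): "
                         f"{missing[:5]}")
    sub = query.loc[scaler.genes]
    return sub.sub(scaler.mean, axis=0).div(scaler.sd, axis=0)
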