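"""Synthetic colony transcriptomes with planted caste and age structure.

Emulates the study design the pipeline expects: established queens and
control workers with known caste labels (latent caste state t = 1 and 0), and
queen-removal (QR) individuals whose latent state is intermediate and
positively correlated with age (gerontocratic succession). Counts follow a
negative binomial with variance ``mu + phi * mu**2``; a planted subset of
genes carries a caste effect (log2 fold change ``+-caste_effect`` scaled by
t), a disjoint subset an age-maturation effect.

Two modelling choices worth knowing about:

* QR latent states are Beta-distributed and coupled to age through a Gaussian
  copula whose correlation is solved numerically so that the realized
  Pearson correlation between t and age matches ``t_age_correlation``.
* Queens' chronological ages are "overwintered" (about 200 days) while
  workers and QR individuals are days-to-weeks old; the *age covariate* that
  drives age-gene expression is the standardized age among young individuals,
  and for queens it is drawn from that same young distribution, modelling
  post-diapause reset of maturation-tracking expression. This keeps planted
  age genes unconfounded with caste, so "does the classifier track caste or
  age?" is a well-posed question on simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocess

__all__ = ["SimulationConfig", "LatentState", "SimulatedDataset",
           "simulate_dataset", "simulate_phenotypes"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the study design (26 training queens, 12 control workers,
    58 classified QR individuals split 24/34 between day 3 and day 12) at a
    desk-scale transcriptome of 500 genes with 50 caste-informative and 50
    age-responsive genes. ``caste_effect`` and ``age_effect`` are log2 fold
    change magnitudes; ``dispersion`` is the negative-binomial phi in
    ``var = mu + phi mu^2``; ``t_age_correlation`` targets the queenness-age
    correlation reported for post-removal individuals (0.48).
    """

    n_genes: int = 500
    n_informative: int = 50
    n_age_genes: int = 50
    n_queens: int = 26
    n_workers: int = 12
    n_qr: int = 58
    caste_effect: float = 1.5
    age_effect: float = 1.0
    dispersion: float = 0.1
    depth_mean: float = 1e6
    depth_cv: float = 0.25
    t_age_correlation: float = 0.48
    seed: int = 0
    allow_gene_overlap: bool = False
    qr_day3_fraction: float = 24 / 58
    qr_t_beta: tuple[float, float] = (2.0, 4.0)

    def validate(self) -> None:
        for name in ("n_genes", "n_queens", "n_workers"):
            if getattr(self, name) < 1:
                raise ValueError(f"config field {name!r} must be >= 1")
        for name in ("n_informative", "n_age_genes", "n_qr"):
            if getattr(self, name) < 0:
                raise ValueError(f"config field {name!r} must be >= 0")
        if not self.allow_gene_overlap and self.n_informative + self.n_age_genes > self.n_genes:
            raise ValueError(
                "config fields n_informative + n_age_genes exceed n_genes "
                "(disjoint planted sets)")
        if self.n_informative > self.n_genes or self.n_age_genes > self.n_genes:
            raise ValueError("config field n_informative/n_age_genes exceeds n_genes")
        if self.caste_effect < 0:
            raise ValueError("config field 'caste_effect' must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("config field 'dispersion' must be > 0")
        if self.depth_mean <= 0:
            raise ValueError("config field 'depth_mean' must be > 0")
        if self.depth_cv < 0:
            raise ValueError("config field 'depth_cv' must be >= 0")
        if not -1 < self.t_age_correlation < 1:
            raise ValueError("config field 't_age_correlation' must lie in (-1, 1)")
        if not 0 <= self.qr_day3_fraction <= 1:
            raise ValueError("config field 'qr_day3_fraction' must lie in [0, 1]")


@dataclass
class LatentState:
    """Ground truth per sample: latent caste state t, age, the age covariate
    actually driving expression, and the library-size factor."""

    table: pd.DataFrame  # index sample_id; columns t, age, age_covariate, size_factor

    @property
    def t(self) -> pd.Series:
        return self.table["t"]

    @property
    def age(self) -> pd.Series:
        return self.table["age"]


@dataclass
class SimulatedDataset:
    counts: pd.DataFrame
    samples: pd.DataFrame
    truth: LatentState
    informative_genes: list[str]
    age_genes: list[str]
    gene_effects: pd.DataFrame  # index gene; columns beta (caste), delta (age)
    config: SimulationConfig

    def write(self, outdir) -> None:
        """Write counts/samples/truth TSVs and gene-set text files."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        preprocess.write_counts(self.counts, out / "counts.tsv")
        preprocess.write_samples(self.samples, out / "samples.tsv")
        self.truth.table.to_csv(out / "truth.tsv", sep="\t", index_label="sample_id")
        self.gene_effects.to_csv(out / "gene_effects.tsv", sep="\t", index_label="gene")
        preprocess.write_gene_set(self.informative_genes, out / "informative_genes.txt")
        preprocess.write_gene_set(self.age_genes, out / "age_genes.txt")


# --- Gaussian-copula calibration -------------------------------------------

def _copula_rho(target: float, beta_ab: tuple[float, float]) -> float:
    """Latent normal correlation giving Pearson cor(t, age) == target.

    t = BetaInv_ab(Phi(z2)) and age = Uniform quantile of Phi(z1); the map
    rho_z -> cor is monotone, evaluated by Gauss-Hermite quadrature and
    inverted by bisection.
    """
    from scipy import stats as sps

    nodes, weights = np.polynomial.hermite_e.hermegauss(48)
    w = weights / np.sqrt(2 * np.pi)
    u = sps.norm.cdf(nodes)
    g_age = u  # uniform quantile, linear in u: correlation is scale-invariant
    g_t = sps.beta.ppf(u, *beta_ab)
    m_age, m_t = w @ g_age, w @ g_t
    s_age = np.sqrt(w @ (g_age - m_age) ** 2)
    s_t = np.sqrt(w @ (g_t - m_t) ** 2)

    def realized(rho: float) -> float:
        z2 = rho * nodes[:, None] + np.sqrt(1 - rho ** 2) * nodes[None, :]
        gt = sps.beta.ppf(sps.norm.cdf(z2), *beta_ab)
        e = w @ ((g_age - m_age)[:, None] * (gt - m_t)) @ w
        return float(e / (s_age * s_t))

    lo, hi = -0.9999, 0.9999
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a seeded count matrix, sample table, and ground truth.

    Counts for gene g in sample i are negative binomial with mean
    ``s_i * depth_mean * p_g * 2**(beta_g * t_i + delta_g * a_i)`` where
    ``p_g`` is the gene's baseline relative abundance, ``beta_g`` is
    ``+-caste_effect`` on planted informative genes (0 elsewhere), ``delta_g``
    is ``+-age_effect`` on planted age genes, and ``a_i`` is the age
    covariate. Identical configs yield identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    n_qr3 = int(round(config.n_qr * config.qr_day3_fraction))
    sample_ids = (
        [f"Q{i + 1:02d}" for i in range(config.n_queens)]
        + [f"W{i + 1:02d}" for i in range(config.n_workers)]
        + [f"QR3_{i + 1:02d}" for i in range(n_qr3)]
        + [f"QR12_{i + 1:02d}" for i in range(config.n_qr - n_qr3)]
    )
    groups = (
        ["queen"] * config.n_queens
        + ["control_worker"] * config.n_workers
        + ["qr_day3"] * n_qr3
        + ["qr_day12"] * (config.n_qr - n_qr3)
    )

    # planted gene sets (disjoint unless overlap is allowed)
    perm = rng.permutation(config.n_genes)
    informative_idx = np.sort(perm[: config.n_informative])
    if config.allow_gene_overlap:
        age_idx = np.sort(rng.choice(config.n_genes, config.n_age_genes, replace=False))
    else:
        age_idx = np.sort(perm[config.n_informative:
                                config.n_informative + config.n_age_genes])
    beta = np.zeros(config.n_genes)
    beta[informative_idx] = config.caste_effect * rng.choice([-1.0, 1.0],
                                                             size=informative_idx.size)
    delta = np.zeros(config.n_genes)
    delta[age_idx] = config.age_effect * rng.choice([-1.0, 1.0], size=age_idx.size)

    # ages: queens overwintered (~200 d), young individuals 3-30 d
    age_q = 200.0 + rng.normal(0.0, 15.0, config.n_queens)
    age_w = rng.uniform(3.0, 30.0, config.n_workers)

    # QR latent state coupled to QR age via a Gaussian copula
    a_beta, b_beta = config.qr_t_beta
    if config.n_qr > 0:
        from scipy import stats as sps

        rho = _copula_rho(config.t_age_correlation, (a_beta, b_beta))
        z1 = rng.standard_normal(config.n_qr)
        z2 = rho * z1 + np.sqrt(1 - rho ** 2) * rng.standard_normal(config.n_qr)
        age_qr = 3.0 + 27.0 * sps.norm.cdf(z1)
        t_qr = np.clip(sps.beta.ppf(sps.norm.cdf(z2), a_beta, b_beta),
                       1e-9, 1 - 1e-9)
    else:
        age_qr = np.empty(0)
        t_qr = np.empty(0)

    t = np.concatenate([np.ones(config.n_queens), np.zeros(config.n_workers), t_qr])
    age = np.concatenate([age_q, age_w, age_qr])

    # age covariate: standardized age among young individuals; queens drawn
    # from the same young distribution (post-diapause maturation reset)
    young = np.concatenate([age_w, age_qr])
    if young.size >= 2 and np.std(young) > 0:
        mu_y, sd_y = float(np.mean(young)), float(np.std(young))
    else:  # pragma: no cover - degenerate designs
        mu_y, sd_y = 16.5, 7.79
    a_cov = (np.concatenate([np.full(config.n_queens, np.nan), young]) - mu_y) / sd_y
    a_cov[: config.n_queens] = rng.standard_normal(config.n_queens)

    # baseline relative abundances and library-size factors
    base = rng.lognormal(mean=0.0, sigma=1.2, size=config.n_genes)
    p_g = base / base.sum()
    n = len(sample_ids)
    if config.depth_cv > 0:
        sigma2 = np.log1p(config.depth_cv ** 2)
        s_i = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)
    else:
        s_i = np.ones(n)

    mu = (s_i[None, :] * config.depth_mean * p_g[:, None]
          * 2.0 ** (beta[:, None] * t[None, :] + delta[:, None] * a_cov[None, :]))
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    counts_df = pd.DataFrame(counts.astype(np.int64), index=pd.Index(genes, name="gene"),
                             columns=sample_ids)
    samples_df = pd.DataFrame({
        "sample_id": sample_ids,
        "group": groups,
        "age": age,
        "ovarian_index": np.nan,
        "dominance": np.nan,
        "queenness": np.nan,
    }).set_index("sample_id", drop=False)
    truth = LatentState(pd.DataFrame({
        "t": t, "age": age, "age_covariate": a_cov, "size_factor": s_i,
    }, index=pd.Index(sample_ids, name="sample_id")))
    effects = pd.DataFrame({"beta": beta, "delta": delta},
                           index=pd.Index(genes, name="gene"))
    return SimulatedDataset(
        counts=counts_df,
        samples=samples_df,
        truth=truth,
        informative_genes=[genes[i] for i in informative_idx],
        age_genes=[genes[i] for i in age_idx],
        gene_effects=effects,
        config=config,
    )


def simulate_phenotypes(truth: LatentState, noise_sd: float = 0.15,
                        seed: int = 0, samples: pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """Fill ovarian index and dominance rating as noisy monotone maps of t.

    Ovarian index is on a 0-1 developmental scale (t plus Gaussian noise);
    dominance is an Elo-like rating centred at 1000 with a 500-point spread,
    built from the same latent state with independent noise of the same
    relative magnitude. Queenness is left unfilled (it is fitted from the
    phenotypes by the pipeline's logistic model). Returns a new SampleTable.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    tab = truth.table
    if tab.isna().any().any():
        raise ValueError("latent state table contains missing values")
    rng = np.random.default_rng(seed)
    t = tab["t"].to_numpy()
    ovarian = t + rng.normal(0.0, noise_sd, t.size)
    dominance = 1000.0 + 500.0 * (t + rng.normal(0.0, noise_sd, t.size))
    if samples is None:
        samples = pd.DataFrame({
            "sample_id": tab.index,
            "group": pd.NA,
            "age": tab["age"].to_numpy(),
            "ovarian_index": np.nan,
            "dominance": np.nan,
            "queenness": np.nan,
        }).set_index("sample_id", drop=False)
    out = samples.copy()
    out.loc[tab.index, "ovarian_index"] = ovarian
    out.loc[tab.index, "dominance"] = dominance
    out["queenness"] = np.nan
    return out
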