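"""Count normalization and differential expression.

TMM scaling factors follow Robinson & Oshlack: per sample vs a reference,
log-ratios (M) and average abundances (A) of genes nonzero in both samples
are double-trimmed (30% each M tail, 5% each A tail) and the factor is
2^(inverse-variance weighted mean M); factors are rescaled to geometric
mean 1. RPKM uses the TMM-adjusted effective library size. Genes with an
RPKM below 1 in at least one sample are flagged low-abundance and excluded
from differential calling. Differential genes come from a fixed-dispersion
negative-binomial conditional exact test (no replicates available to
estimate tagwise dispersion from), flagged at FDR < 0.05 and linear fold
change >= 2 in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .interactions import bh_qvalues

__all__ = [
    "CountMatrix",
    "ExpressionResult",
    "tmm_factors",
    "rpkm",
    "low_abundance_filter",
    "call_degs",
    "nb_exact_test",
]


@dataclass
class CountMatrix:
    """Gene x sample integer counts with exonic lengths for RPKM."""

    gene_ids: list[str]
    samples: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples)
    exonic_lengths: np.ndarray  # bp per gene

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.exonic_lengths = np.asarray(self.exonic_lengths)
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError("counts shape inconsistent with gene/sample lists")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")
        if (self.exonic_lengths < 1).any():
            raise ValueError("exonic lengths must be >= 1")

    @property
    def lib_size(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.samples)

    @classmethod
    def from_tsv(cls, path, exonic_lengths: dict[str, int]) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        lengths = np.array([exonic_lengths[g] for g in df.index])
        return cls(
            gene_ids=list(df.index),
            samples=list(df.columns),
            counts=df.to_numpy(),
            exonic_lengths=lengths,
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


def _upper_quartile_ref(counts: np.ndarray) -> int:
    """Index of the sample whose upper quartile of scaled counts is closest
    to the mean upper quartile across samples."""
    lib = counts.sum(axis=0)
    uq = np.array(
        [np.quantile(counts[:, k] / lib[k], 0.75) for k in range(counts.shape[1])]
    )
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference (log2 scale -> linear)."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 1.0
    o = obs[ok] / n_obs
    r = ref[ok] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
    n = m.size
    # double trimming by rank, keeping the central mass of both M and A
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_factors(
    counts: CountMatrix | np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: int | None = None,
) -> np.ndarray:
    """TMM scaling factor per sample, rescaled to geometric mean exactly 1."""
    x = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = x.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    ref = _upper_quartile_ref(x) if ref_sample is None else ref_sample
    factors = np.ones(x.shape[1])
    for k in range(x.shape[1]):
        if k == ref:
            continue
        factors[k] = _tmm_pair(x[:, k], x[:, ref], lib[k], lib[ref], trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def rpkm(
    counts: np.ndarray,
    exonic_lengths: np.ndarray,
    effective_lib_sizes: np.ndarray,
) -> np.ndarray:
    """count * 1e9 / (effective_lib_size * exonic_length)."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(exonic_lengths, dtype=float)
    libs = np.asarray(effective_lib_sizes, dtype=float)
    if (lengths < 1).any():
        raise ValueError("exonic lengths must be >= 1")
    if (libs <= 0).any():
        raise ValueError("effective library sizes must be > 0")
    return counts * 1e9 / (libs[None, :] * lengths[:, None])


def low_abundance_filter(rpkm_matrix: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    """Flag genes with RPKM below ``threshold`` in at least one sample."""
    return (np.asarray(rpkm_matrix) < threshold).any(axis=1)


def nb_exact_test(
    y1: int, y2: int, n1: float, n2: float, dispersion: float
) -> float:
    """Two-sided NB exact test conditional on the pair total.

    Under H0 the common relative abundance is (y1+y2)/(n1+n2); the p-value
    sums, over all splits of the total, the conditional probabilities no
    larger than the observed one (double-tail form). Degenerate totals give
    p = 1.
    """
    total = int(y1 + y2)
    if total == 0:
        return 1.0
    lam = total / (n1 + n2)
    mu1, mu2 = lam * n1, lam * n2
    # NB parameterised by mean mu and dispersion phi: var = mu + phi*mu^2
    r = 1.0 / dispersion
    a = np.arange(total + 1)
    logp1 = stats.nbinom.logpmf(a, r, r / (r + mu1))
    logp2 = stats.nbinom.logpmf(total - a, r, r / (r + mu2))
    logjoint = logp1 + logp2
    logjoint -= logjoint.max()
    joint = np.exp(logjoint)
    joint /= joint.sum()
    p_obs = joint[y1]
    # include all outcomes as or less likely than observed (with a small
    # relative slack so float noise cannot drop the observed outcome itself)
    return float(min(1.0, joint[joint <= p_obs * (1 + 1e-12)].sum()))


@dataclass
class ExpressionResult:
    gene_ids: list[str]
    rpkm: np.ndarray            # (n_genes, 2)
    log2_fc: np.ndarray         # condition2 vs condition1
    fdr: np.ndarray
    deg_flag: np.ndarray        # 'up' | 'down' | 'none'
    low_abundance: np.ndarray   # bool

    def flag_of(self, gene_id: str) -> str:
        return str(self.deg_flag[self.gene_ids.index(gene_id)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rpkm_1": self.rpkm[:, 0],
                "rpkm_2": self.rpkm[:, 1],
                "log2_fc": self.log2_fc,
                "fdr": self.fdr,
                "deg_flag": self.deg_flag,
                "low_abundance": self.low_abundance,
            },
            index=pd.Index(self.gene_ids, name="gene_id"),
        )


def call_degs(
    counts: CountMatrix,
    dispersion: float = 0.1,
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
    rpkm_threshold: float = 1.0,
) -> ExpressionResult:
    """TMM-normalize, compute RPKM, filter low-abundance genes and run the
    fixed-dispersion NB exact test between exactly two conditions."""
    if counts.counts.shape[1] != 2:
        raise ValueError("differential calling requires exactly 2 conditions")
    x = counts.counts
    lib = counts.lib_size.astype(float)
    factors = tmm_factors(counts)
    eff = lib * factors
    rp = rpkm(x, counts.exonic_lengths, eff)
    low = low_abundance_filter(rp, rpkm_threshold)
    # moderated fold change (0.5 pseudocount on the normalized scale)
    cpm = (x + 0.5) / eff[None, :] * 1e6
    log2_fc = np.log2(cpm[:, 1] / cpm[:, 0])
    pvals = np.ones(x.shape[0])
    tested = ~low
    for g in np.nonzero(tested)[0]:
        pvals[g] = nb_exact_test(int(x[g, 0]), int(x[g, 1]), eff[0], eff[1], dispersion)
    fdr = np.ones(x.shape[0])
    if tested.any():
        fdr[tested] = bh_qvalues(pvals[tested])
    flags = np.full(x.shape[0], "none", dtype=object)
    fc = 2.0 ** log2_fc
    up = tested & (fdr < fdr_max) & (fc >= fc_min)
    down = tested & (fdr < fdr_max) & (fc <= 1.0 / fc_min)
    flags[up] = "up"
    flags[down] = "down"
    return ExpressionResult(
        gene_ids=list(counts.gene_ids),
        rpkm=rp,
        log2_fc=log2_fc,
        fdr=fdr,
        deg_flag=flags,
        low_abundance=low,
    )
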