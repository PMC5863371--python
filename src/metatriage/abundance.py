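"""Low-count filtering and normalization.

Implements the count-processing conventions of a two-condition
metatranscriptome workflow: a nearest-rank percentile filter on per-contig
total counts, transcripts-per-million (TPM) from effective lengths,
median-of-ratios size factors, trimmed-mean-of-M-values (TMM) factors and
log2 counts per million.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix


@dataclass
class SizeFactors:
    """Per-sample positive scaling factors with the method that produced
    them (``median_ratio`` or ``tmm``). TMM factors multiply to 1."""

    factors: pd.Series
    method: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")


@dataclass
class AbundanceTable:
    """TPM per contig x sample plus the effective lengths used."""

    tpm: pd.DataFrame
    effective_lengths: pd.Series


def percentile_filter(
    counts: CountMatrix,
    percentile: float | None = None,
    absolute_min: int | None = None,
) -> tuple[CountMatrix, int]:
    """Drop contigs whose total count across all samples falls below a
    threshold.

    The threshold is either ``absolute_min`` or the nearest-rank
    ``percentile`` of the per-contig total distribution (sorted totals,
    index ``ceil(p/100 * n)``). Rows with total >= threshold are kept, so
    ties at the threshold survive.

    Returns the filtered matrix and the integer threshold applied.
    """
    if counts.counts.empty:
        raise ValueError("empty count matrix")
    if (percentile is None) == (absolute_min is None):
        raise ValueError("give exactly one of percentile or absolute_min")
    totals = counts.counts.sum(axis=1)
    if absolute_min is not None:
        threshold = int(absolute_min)
    else:
        if not 0 < percentile < 100:
            raise ValueError(f"percentile must be in (0, 100), got {percentile}")
        ordered = np.sort(totals.values)
        rank = int(np.ceil(percentile / 100.0 * len(ordered)))  # nearest rank, 1-based
        threshold = int(ordered[max(rank, 1) - 1])
    keep = totals >= threshold
    if not keep.any():
        warnings.warn("count filter removed every contig", stacklevel=2)
    filtered = CountMatrix(counts.counts.loc[keep].copy(), dict(counts.conditions))
    return filtered, threshold


def tpm_column(counts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """TPM for one sample: rate c/l renormalized to sum to 1e6.

    An all-zero column stays all-zero.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        return np.zeros_like(rate)
    return rate / total * 1e6


def tpm_table(counts: CountMatrix, lengths: dict[str, float]) -> AbundanceTable:
    """TPM for every sample column of a count matrix."""
    missing = [c for c in counts.contig_ids if c not in lengths]
    if missing:
        raise ValueError(f"missing effective lengths for {missing[:5]}...")
    lvec = pd.Series({c: float(lengths[c]) for c in counts.contig_ids})
    mat = pd.DataFrame(
        {s: tpm_column(counts.counts[s].values, lvec.values) for s in counts.sample_ids},
        index=counts.contig_ids,
    )
    return AbundanceTable(tpm=mat, effective_lengths=lvec)


def median_ratio_size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    s_j = median over all-positive contigs of c_ij / geomean_i(c_i.),
    the normalization convention of median-based empirical-Bayes DE.
    """
    mat = counts.counts.values.astype(float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no contig has positive counts in every sample; apply the count "
            "filter before computing median-ratio size factors"
        )
    sub = mat[allpos]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.exp(np.log(sub) - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    return SizeFactors(pd.Series(factors, index=counts.sample_ids), "median_ratio")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float) -> float:
    """Weighted trimmed mean of M-values of one sample against the
    reference; returns the factor on the natural scale (2**TMM)."""
    n_obs = obs.sum()
    n_ref = ref.sum()
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        warnings.warn("no co-expressed contigs with reference; TMM factor 1", stacklevel=3)
        return 1.0
    o = obs[keep] / n_obs
    r = ref[keep] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic (delta-method) variance of M as inverse weight
    w = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (n_ref * ref[keep])
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank(method="average").values
    rank_a = pd.Series(a).rank(method="average").values
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not sel.any() or w[sel].sum() == 0:
        return 1.0
    tmm = (m[sel] / w[sel]).sum() / (1.0 / w[sel]).sum()
    return float(2.0 ** tmm)


def tmm_factors(
    counts: CountMatrix,
    reference: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> SizeFactors:
    """Trimmed mean of M-values normalization factors.

    For each sample against the reference, the weighted mean of log ratios
    (M) is taken after trimming ``trim_m`` from each tail of M and
    ``trim_a`` from each tail of average abundance (A); weights are the
    inverse asymptotic variance of M. Factors are rescaled so their
    product is 1. The reference defaults to the sample whose upper
    quartile (of the count fraction) is closest to the mean upper
    quartile.
    """
    mat = counts.counts.values.astype(float)
    libsize = mat.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("every sample must have positive library size")
    samples = counts.sample_ids
    if reference is None:
        uq = np.array(
            [np.quantile(mat[:, j] / libsize[j], 0.75) for j in range(len(samples))]
        )
        reference = samples[int(np.argmin(np.abs(uq - uq.mean())))]
    ref_idx = samples.index(reference)
    ref = mat[:, ref_idx]
    raw = np.array(
        [
            1.0 if j == ref_idx else _tmm_pair(mat[:, j], ref, trim_m, trim_a)
            for j in range(len(samples))
        ]
    )
    # centre so the factors multiply to 1
    raw = raw / np.exp(np.mean(np.log(raw)))
    return SizeFactors(pd.Series(raw, index=samples), "tmm")


def log2_cpm(
    counts: CountMatrix,
    size_factors: SizeFactors | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million with a prior count to keep zeros finite:
    log2((c + prior) / (N*s + 2*prior) * 1e6)."""
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    mat = counts.counts.values.astype(float)
    libsize = mat.sum(axis=0)
    s = (
        np.ones(len(counts.sample_ids))
        if size_factors is None
        else size_factors.factors.reindex(counts.sample_ids).values
    )
    eff = libsize * s
    out = np.log2((mat + prior_count) / (eff + 2.0 * prior_count)[None, :] * 1e6)
    return pd.DataFrame(out, index=counts.contig_ids, columns=counts.sample_ids)
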