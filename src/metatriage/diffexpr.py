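"""Two-condition empirical-Bayes negative-binomial differential expression.

Model: the count of contig g in sample j is NB(r_gj, q_g) with
r_gj = r_g * s_j (s_j the sample size factor) and a conjugate Beta(alpha,
beta) prior on q_g shared across contigs. Under equivalent expression
(EE) one q_g serves all samples; under differential expression (DE) each
condition draws its own q. Integrating q out gives closed-form marginal
likelihoods, and the posterior probability of differential expression is

    PPDE_g = pi * f_DE,g / ((1 - pi) * f_EE,g + pi * f_DE,g)

with mixing weight pi estimated by EM alongside (alpha, beta). The
per-contig NB size r_g comes from method-of-moments on size-factor-scaled
counts. Contigs observed in only one condition ("infinity genes") keep a
finite fold change through an epsilon substituted for the zero mean.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, gammaln

from .abundance import AbundanceTable, SizeFactors, log2_cpm
from .core import CONTROL, TREATMENT, CountMatrix

R_CAP = 1e8  # NB size for contigs whose sample variance <= mean (Poisson-like)

PRESENT_BOTH = "both"
TREATMENT_ONLY = "treatment_only"
CONTROL_ONLY = "control_only"


@dataclass
class EBHyperparams:
    alpha: float
    beta: float
    pi: float
    n_iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")


def classify_presence(row: np.ndarray, labels: list[str]) -> str:
    """Presence class from condition-wise count sums (> 0 means present)."""
    row = np.asarray(row)
    labels = np.asarray(labels)
    in_control = row[labels == CONTROL].sum() > 0
    in_treatment = row[labels == TREATMENT].sum() > 0
    if not in_control and not in_treatment:
        raise ValueError("all-zero row reached presence classification")
    if in_control and in_treatment:
        return PRESENT_BOTH
    return TREATMENT_ONLY if in_treatment else CONTROL_ONLY


def fold_change(
    mean_treatment: float, mean_control: float, epsilon: float
) -> tuple[float, float]:
    """Treatment/control fold change with epsilon substituted for a zero
    mean, so condition-exclusive contigs get a finite value."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if mean_treatment == 0 and mean_control == 0:
        raise ValueError("both condition means are zero")
    t = mean_treatment if mean_treatment > 0 else epsilon
    c = mean_control if mean_control > 0 else epsilon
    fc = t / c
    return fc, float(np.log2(fc))


def default_epsilon(mean_control: np.ndarray, mean_treatment: np.ndarray) -> float:
    """Half the smallest nonzero condition mean in the dataset — keeps
    every exclusive contig's |fold change| above any finite one at the
    same abundance."""
    pooled = np.concatenate([np.asarray(mean_control), np.asarray(mean_treatment)])
    nonzero = pooled[pooled > 0]
    if nonzero.size == 0:
        raise ValueError("no nonzero condition means")
    return float(nonzero.min() / 2.0)


# ---------------------------------------------------------------------------
# Empirical-Bayes fit

def _moment_sizes(scaled: np.ndarray, idx_c: np.ndarray, idx_t: np.ndarray) -> np.ndarray:
    """Per-contig NB size by method of moments: overall mean with the
    variance pooled within conditions, so a real group difference is not
    absorbed into the dispersion."""
    m = scaled.mean(axis=1)
    nc, nt = len(idx_c), len(idx_t)
    vc = scaled[:, idx_c].var(axis=1, ddof=1)
    vt = scaled[:, idx_t].var(axis=1, ddof=1)
    v = ((nc - 1) * vc + (nt - 1) * vt) / (nc + nt - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(v > m, m * m / (v - m), R_CAP)
    r = np.clip(r, 1e-8, R_CAP)
    return r


def _condition_indices(counts: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    idx_c = np.array(
        [i for i, s in enumerate(counts.sample_ids) if counts.conditions[s] == CONTROL]
    )
    idx_t = np.array(
        [i for i, s in enumerate(counts.sample_ids) if counts.conditions[s] == TREATMENT]
    )
    return idx_c, idx_t


def fit_eb_nb(
    counts: CountMatrix,
    size_factors: SizeFactors,
    max_rounds: int = 5,
    tol: float = 1e-3,
    pi_init: float = 0.5,
) -> tuple[EBHyperparams, pd.Series]:
    """Fit the EE/DE mixture by EM and return hyperparameters plus the
    per-contig PPDE.

    E-step: PPDE under current (alpha, beta, pi). M-step: pi is the mean
    PPDE; (alpha, beta) maximise the PPDE-weighted log marginal
    (Nelder-Mead on the log scale). Iterates ``max_rounds`` times or
    until |delta pi| < ``tol``. Deterministic given inputs.
    """
    ctrl = counts.samples_of(CONTROL)
    trt = counts.samples_of(TREATMENT)
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need >= 2 samples per condition")
    x = counts.counts.values.astype(float)
    if (x.sum(axis=1) == 0).any():
        raise ValueError("all-zero rows present; apply the count filter first")
    s = size_factors.factors.reindex(counts.sample_ids).values
    scaled = x / s
    idx_c, idx_t = _condition_indices(counts)
    r = _moment_sizes(scaled, idx_c, idx_t)

    sum_s = s.sum()
    sum_s_c = s[idx_c].sum()
    sum_s_t = s[idx_t].sum()
    R_all = r * sum_s
    R_c = r * sum_s_c
    R_t = r * sum_s_t
    X_all = x.sum(axis=1)
    X_c = x[:, idx_c].sum(axis=1)
    X_t = x[:, idx_t].sum(axis=1)

    # per-sample combinatorial term: identical in the EE and DE marginals,
    # so it is constant in (alpha, beta, pi) and cancels in PPDE
    r_gj = r[:, None] * s[None, :]
    log_comb = (gammaln(x + r_gj) - gammaln(r_gj) - gammaln(x + 1.0)).sum(axis=1)

    def log_marginals(alpha: float, beta: float) -> tuple[np.ndarray, np.ndarray]:
        base = betaln(alpha, beta)
        lee = betaln(alpha + R_all, beta + X_all) - base
        lde = (
            betaln(alpha + R_c, beta + X_c)
            + betaln(alpha + R_t, beta + X_t)
            - 2.0 * base
        )
        return lee, lde

    def ppde_of(lee, lde, pi):
        # PPDE = 1 / (1 + (1-pi)/pi * exp(lee - lde)), stable in log space
        with np.errstate(over="ignore"):
            odds = np.exp(np.clip(lee - lde, -700, 700)) * ((1.0 - pi) / max(pi, 1e-300))
        return 1.0 / (1.0 + odds)

    alpha, beta, pi = 1.0, 1.0, float(pi_init)
    converged = False
    rounds = 0
    lee, lde = log_marginals(alpha, beta)
    for rounds in range(1, max_rounds + 1):
        w = ppde_of(lee, lde, pi)
        new_pi = float(np.clip(w.mean(), 1e-6, 1.0 - 1e-6))

        def neg_q(params):
            a, b = np.exp(params)
            l_ee, l_de = log_marginals(a, b)
            return -float(((1.0 - w) * l_ee + w * l_de).sum())

        opt = minimize(
            neg_q,
            x0=np.log([alpha, beta]),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-4, "maxiter": 400},
        )
        alpha, beta = np.exp(opt.x)
        lee, lde = log_marginals(alpha, beta)
        delta = abs(new_pi - pi)
        pi = new_pi
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM did not converge within {max_rounds} rounds (|dpi|>{tol})",
            stacklevel=2,
        )
    ppde = pd.Series(ppde_of(lee, lde, pi), index=counts.contig_ids, name="ppde")
    # finite-marginal sanity (log_comb is the dropped constant part)
    if not np.isfinite(log_comb).all():
        raise FloatingPointError("non-finite marginal likelihood term")
    hyper = EBHyperparams(float(alpha), float(beta), pi, rounds, converged)
    return hyper, ppde


def posterior_fold_change(
    counts: CountMatrix, size_factors: SizeFactors, hyper: EBHyperparams
) -> pd.Series:
    """Posterior (shrunken) treatment/control fold change from the
    posterior mean of the NB probability parameter per condition."""
    x = counts.counts.values.astype(float)
    s = size_factors.factors.reindex(counts.sample_ids).values
    idx_c, idx_t = _condition_indices(counts)
    r = _moment_sizes(x / s, idx_c, idx_t)
    labels = np.array([counts.conditions[j] for j in counts.sample_ids])
    out = {}
    means = {}
    for cond, mask in ((CONTROL, labels == CONTROL), (TREATMENT, labels == TREATMENT)):
        R = r * s[mask].sum()
        X = x[:, mask].sum(axis=1)
        q_hat = (hyper.alpha + R) / (hyper.alpha + R + hyper.beta + X)
        means[cond] = r * (1.0 - q_hat) / q_hat
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = means[TREATMENT] / means[CONTROL]
    return pd.Series(fc, index=counts.contig_ids, name="posterior_fc")


def declare_de(ppde: pd.Series, threshold: float = 0.95) -> tuple[pd.Series, float]:
    """DE calls at a PPDE threshold plus the posterior soft FDR estimate,
    mean(1 - PPDE) over called contigs (0 when nothing is called)."""
    if ((ppde < 0) | (ppde > 1)).any():
        raise ValueError("ppde outside [0, 1]")
    calls = ppde >= threshold
    soft_fdr = float((1.0 - ppde[calls]).mean()) if calls.any() else 0.0
    return calls.rename("de_call"), soft_fdr


def de_table(
    counts: CountMatrix,
    size_factors: SizeFactors,
    abundance: AbundanceTable,
    hyper: EBHyperparams,
    ppde: pd.Series,
    threshold: float = 0.95,
    epsilon: float | None = None,
) -> pd.DataFrame:
    """Assemble the per-contig DE result table: PPDE, raw and posterior
    fold changes (treatment/control), presence class and DE call."""
    labels = [counts.conditions[j] for j in counts.sample_ids]
    tpm = abundance.tpm.reindex(counts.contig_ids)
    ctrl = counts.samples_of(CONTROL)
    trt = counts.samples_of(TREATMENT)
    mean_c = tpm[ctrl].mean(axis=1).values
    mean_t = tpm[trt].mean(axis=1).values
    eps = default_epsilon(mean_c, mean_t) if epsilon is None else float(epsilon)
    rows = []
    x = counts.counts.values
    scaled = counts.counts.values.astype(float) / size_factors.factors.reindex(
        counts.sample_ids
    ).values
    r = _moment_sizes(scaled, *_condition_indices(counts))
    post_fc = posterior_fold_change(counts, size_factors, hyper)
    calls, _soft = declare_de(ppde.reindex(counts.contig_ids), threshold)
    for i, cid in enumerate(counts.contig_ids):
        presence = classify_presence(x[i], labels)
        fc, lfc = fold_change(mean_t[i], mean_c[i], eps)
        rows.append(
            {
                "contig_id": cid,
                "ppde": float(ppde[cid]),
                "raw_fc": fc,
                "posterior_fc": float(post_fc[cid]),
                "log2_fc": lfc,
                "presence_class": presence,
                "de_call": bool(calls[cid]),
                "r_g": float(r[i]),
                "mean_tpm_control": float(mean_c[i]),
                "mean_tpm_treatment": float(mean_t[i]),
            }
        )
    return pd.DataFrame(rows).set_index("contig_id")


def ma_table(
    counts: CountMatrix,
    size_factors: SizeFactors,
    epsilon: float | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Per-contig MA-plot coordinates: mean log2 CPM (x), epsilon-finite
    log2 fold change treatment/control on the CPM scale (y), and the
    presence class. One output row per input contig."""
    cpm_log = log2_cpm(counts, size_factors, prior_count)
    x = counts.counts.values.astype(float)
    s = size_factors.factors.reindex(counts.sample_ids).values
    lib = x.sum(axis=0) * s
    cpm = x / lib[None, :] * 1e6
    labels = np.array([counts.conditions[j] for j in counts.sample_ids])
    mean_c = cpm[:, labels == CONTROL].mean(axis=1)
    mean_t = cpm[:, labels == TREATMENT].mean(axis=1)
    eps = default_epsilon(mean_c, mean_t) if epsilon is None else float(epsilon)
    rows = []
    for i, cid in enumerate(counts.contig_ids):
        _fc, lfc = fold_change(mean_t[i], mean_c[i], eps)
        rows.append(
            {
                "contig_id": cid,
                "mean_log2_cpm": float(cpm_log.iloc[i].mean()),
                "log2_fc": lfc,
                "presence_class": classify_presence(x[i], list(labels)),
            }
        )
    return pd.DataFrame(rows).set_index("contig_id")
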