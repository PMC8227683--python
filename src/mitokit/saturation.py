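"""Substitution-saturation screening.

Saturation is diagnosed by comparing uncorrected p-distances with pairwise
maximum-likelihood distances under GTR+Gamma+I: as multiple substitutions
accumulate, p-distances plateau while corrected distances keep growing, so
the correlation between the two decays.  Partitions whose correlation falls
below a threshold, or which rank in the bottom few, are flagged as
saturated.

The GTR rate matrix is normalised to mean rate 1 across the non-invariant
mixture; rate heterogeneity uses k mean-preserving discrete-gamma
categories plus a point mass at rate 0 for the invariant proportion.
Pairwise distances are optimised by bounded 1-D search on the expected
number of substitutions per site, capped at 10 with a saturation flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist, pearsonr, spearmanr

DISTANCE_CAP = 10.0
_BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

#: exchangeability parameter order (GT is the reference, fixed to 1)
EXCH_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
_EXCH_IDX = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; gaps and ambiguity codes -> -1 (excluded pairwise)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class SubstitutionModel:
    """GTR+Gamma+I: stationary frequencies pi (A,C,G,T), exchangeabilities
    r (AC,AG,AT,CG,CT,GT; GT = 1), gamma shape alpha, invariant proportion
    p_inv, and k discrete gamma categories."""

    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    exchangeabilities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    alpha: float = 1.0
    p_inv: float = 0.0
    k: int = 4

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.pi), 1.0, abs_tol=1e-6):
            raise ValueError("base frequencies must sum to 1")
        if min(self.pi) <= 0 or min(self.exchangeabilities) <= 0:
            raise ValueError("frequencies and exchangeabilities must be positive")
        if self.alpha <= 0 or not (0 <= self.p_inv < 1):
            raise ValueError("alpha > 0 and 0 <= p_inv < 1 required")


def jukes_cantor_model(alpha: float = 1e6) -> SubstitutionModel:
    """Equal-frequency, equal-rate limit; large alpha makes Gamma ~ constant."""
    return SubstitutionModel(alpha=alpha)


def gamma_category_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean-preserving category rates of the discrete Gamma(alpha, alpha)."""
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate(([0.0], bounds, [np.inf]))
    upper = gammainc(alpha + 1.0, np.where(np.isinf(edges[1:]), np.inf, edges[1:] * alpha))
    lower = gammainc(alpha + 1.0, edges[:-1] * alpha)
    return k * (upper - lower)


def rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Normalised GTR generator: expected rate 1 over the non-invariant
    fraction of sites (rows sum to zero)."""
    pi = np.asarray(model.pi)
    Q = np.zeros((4, 4))
    for r, (i, j) in zip(model.exchangeabilities, _EXCH_IDX):
        Q[i, j] = r * pi[j]
        Q[j, i] = r * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    return Q / (mu * (1.0 - model.p_inv))


@dataclass(frozen=True)
class _Eigen:
    rates: np.ndarray
    lam: np.ndarray
    right: np.ndarray  # D^{-1/2} U
    left: np.ndarray  # U^T D^{1/2}


def _eigen(model: SubstitutionModel) -> _Eigen:
    pi = np.asarray(model.pi)
    Q = rate_matrix(model)
    d = np.sqrt(pi)
    B = (Q * d[:, None]) / d[None, :]
    lam, U = np.linalg.eigh((B + B.T) / 2.0)
    return _Eigen(
        rates=gamma_category_rates(model.alpha, model.k),
        lam=lam,
        right=U / d[:, None],
        left=U.T * d[None, :],
    )


def _mixture_probs(eig: _Eigen, model: SubstitutionModel, d: float) -> np.ndarray:
    """Joint probabilities f(x, y) = pi_x * P_mix(x -> y) at distance d."""
    pi = np.asarray(model.pi)
    P = np.zeros((4, 4))
    for rho in eig.rates:
        P += eig.right @ (np.exp(eig.lam * rho * d)[:, None] * eig.left)
    P *= (1.0 - model.p_inv) / model.k
    P += model.p_inv * np.eye(4)
    return pi[:, None] * np.clip(P, 1e-300, None)


def count_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """4x4 site-pattern counts with pairwise deletion of non-ACGT sites."""
    ok = (a >= 0) & (b >= 0)
    if not ok.any():
        return np.zeros((4, 4))
    code = a[ok].astype(np.int64) * 4 + b[ok]
    return np.bincount(code, minlength=16).reshape(4, 4).astype(float)


def p_distance(a: str | np.ndarray, b: str | np.ndarray) -> float:
    """Proportion of differing sites, pairwise deletion; NaN when no
    comparable sites remain."""
    ea = encode(a) if isinstance(a, str) else a
    eb = encode(b) if isinstance(b, str) else b
    if ea.shape != eb.shape:
        raise ValueError("sequences must be aligned to equal length")
    ok = (ea >= 0) & (eb >= 0)
    n = int(ok.sum())
    return float((ea[ok] != eb[ok]).mean()) if n else math.nan


def _pair_loglik(N: np.ndarray, d: float, model: SubstitutionModel, eig: _Eigen) -> float:
    return float((N * np.log(_mixture_probs(eig, model, d))).sum())


def _optimize_distance(
    N: np.ndarray, model: SubstitutionModel, eig: _Eigen, xatol: float = 1e-8
) -> tuple[float, bool]:
    if N.sum() == 0:
        return math.nan, False
    if np.trace(N) == N.sum():
        return 0.0, False
    res = minimize_scalar(
        lambda d: -_pair_loglik(N, d, model, eig),
        bounds=(1e-9, DISTANCE_CAP),
        method="bounded",
        options={"xatol": xatol},
    )
    d = float(res.x)
    saturated = d > DISTANCE_CAP * 0.995
    return (DISTANCE_CAP if saturated else d), saturated


def gtr_gi_distance(
    a: str | np.ndarray, b: str | np.ndarray, model: SubstitutionModel
) -> float:
    """Pairwise ML distance (substitutions/site) under GTR+Gamma+I.

    Maximises the likelihood of the site-pattern counts over the branch
    length by bounded search; saturated pairs return the cap (10)."""
    ea = encode(a) if isinstance(a, str) else a
    eb = encode(b) if isinstance(b, str) else b
    if ea.shape != eb.shape:
        raise ValueError("sequences must be aligned to equal length")
    d, _ = _optimize_distance(count_matrix(ea, eb), model, _eigen(model))
    return d


@dataclass
class DistanceMatrix:
    taxa: tuple[str, ...]
    values: np.ndarray
    kind: str  # "p" | "gtr_gi"
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.taxa), k=-1)
        return self.values[i, j]

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for t, row in zip(self.taxa, self.values):
                fh.write(t.replace(" ", "_").ljust(12) + " ".join(f"{v:.6f}" for v in row) + "\n")


def p_distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    taxa = tuple(alignment)
    enc = [encode(alignment[t]) for t in taxa]
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            D[i, j] = D[j, i] = p_distance(enc[i], enc[j])
    return DistanceMatrix(taxa=taxa, values=D, kind="p")


def gtr_gi_distance_matrix(alignment: dict[str, str], model: SubstitutionModel) -> DistanceMatrix:
    taxa = tuple(alignment)
    enc = [encode(alignment[t]) for t in taxa]
    eig = _eigen(model)
    n = len(taxa)
    D = np.zeros((n, n))
    flagged = []
    for i in range(n):
        for j in range(i):
            d, sat = _optimize_distance(count_matrix(enc[i], enc[j]), model, eig)
            D[i, j] = D[j, i] = d
            if sat:
                flagged.append((taxa[j], taxa[i]))
    return DistanceMatrix(taxa=taxa, values=D, kind="gtr_gi", saturated_pairs=flagged)


def empirical_frequencies(alignment: dict[str, str]) -> tuple[float, float, float, float]:
    counts = np.zeros(4)
    for seq in alignment.values():
        e = encode(seq)
        counts += np.bincount(e[e >= 0], minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("alignment contains no unambiguous bases")
    freqs = np.clip(counts / total, 1e-4, None)
    freqs = freqs / freqs.sum()
    return tuple(freqs)


def estimate_model(
    alignment: dict[str, str],
    k: int = 4,
    max_pairs: int = 60,
    seed: int = 0,
    maxiter: int = 400,
    n_restarts: int = 2,
) -> SubstitutionModel:
    """Fit GTR+Gamma+I to a multi-taxon alignment.

    Base frequencies are empirical; (exchangeabilities, alpha, p_inv)
    maximise the sum of pairwise log-likelihoods, each at its own profiled
    distance.  Optimisation is Nelder-Mead over the log/logit-transformed
    parameters with two fixed starts, each polished by up to *n_restarts*
    restarts from the incumbent (the alpha/p_inv ridge is nearly flat and
    a single simplex run can terminate early on it); pairs are subsampled
    (seeded) to at most *max_pairs* to keep the composite likelihood
    tractable.  A two-sequence alignment is accepted but weakly
    identifiable.
    """
    taxa = list(alignment)
    if len(taxa) < 2:
        raise ValueError("need at least two sequences")
    enc = {t: encode(alignment[t]) for t in taxa}
    pairs = [(a, b) for i, a in enumerate(taxa) for b in taxa[i + 1 :]]
    rng = np.random.default_rng(seed)
    if len(pairs) > max_pairs:
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    counts = [count_matrix(enc[a], enc[b]) for a, b in pairs]
    counts = [N for N in counts if N.sum() > 0 and np.trace(N) < N.sum()]
    if not counts:
        raise ValueError("degenerate alignment: no variable, comparable pairs")
    pi = empirical_frequencies(alignment)

    def unpack(theta: np.ndarray) -> SubstitutionModel:
        r = tuple(np.exp(theta[:5])) + (1.0,)
        alpha = float(np.exp(theta[5]))
        p_inv = float(1.0 / (1.0 + np.exp(-theta[6])))
        return SubstitutionModel(pi=pi, exchangeabilities=r, alpha=alpha, p_inv=min(p_inv, 0.95), k=k)

    def objective(theta: np.ndarray) -> float:
        if np.any(np.abs(theta[:6]) > 8):
            return 1e12
        model = unpack(theta)
        eig = _eigen(model)
        total = 0.0
        for N in counts:
            d, _ = _optimize_distance(N, model, eig, xatol=1e-5)
            total += _pair_loglik(N, d, model, eig)
        return -total

    starts = [
        np.array([0.0, np.log(4.0), 0.0, 0.0, np.log(4.0), np.log(0.5), -2.0]),
        np.array([0.0, 0.0, 0.0, 0.0, 0.0, np.log(2.0), -1.0]),
    ]
    nm_options = {"maxiter": maxiter, "fatol": 1e-3, "xatol": 1e-3}
    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead", options=nm_options)
        for _ in range(n_restarts):
            polish = minimize(objective, res.x, method="Nelder-Mead", options=nm_options)
            improved = polish.fun < res.fun - 0.5
            if polish.fun < res.fun:
                res = polish
            if not improved:
                break
        if best is None or res.fun < best.fun:
            best = res
    return unpack(best.x)


@dataclass
class SaturationReport:
    """Per-partition correlation between corrected and p distances."""

    partitions: dict[str, dict] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"partition": name, **stats} for name, stats in self.partitions.items()]
        return pd.DataFrame(rows).sort_values("correlation", ignore_index=True)

    def flagged(self) -> list[str]:
        return [p for p, s in self.partitions.items() if s["flagged"]]


def saturation_screen(
    partitions: dict[str, dict[str, str]],
    models: dict[str, SubstitutionModel] | SubstitutionModel,
    threshold: float = 0.9,
    bottom_k: int = 3,
    method: str = "pearson",
) -> SaturationReport:
    """Correlate corrected vs uncorrected pairwise distances per partition.

    A partition is flagged when its correlation falls below *threshold* OR
    ranks in the bottom *bottom_k*.  Partitions with fewer than 3 usable
    pairs, or constant distances, are excluded with a warning entry."""
    import warnings as _warnings

    corr_fn = pearsonr if method == "pearson" else spearmanr
    report = SaturationReport()
    results: dict[str, dict] = {}
    for name, alignment in partitions.items():
        model = models[name] if isinstance(models, dict) else models
        pmat = p_distance_matrix(alignment)
        cmat = gtr_gi_distance_matrix(alignment, model)
        p = pmat.lower_triangle()
        c = cmat.lower_triangle()
        ok = ~(np.isnan(p) | np.isnan(c))
        p, c = p[ok], c[ok]
        if len(p) < 3 or np.ptp(p) == 0 or np.ptp(c) == 0:
            _warnings.warn(f"partition {name}: fewer than 3 usable pairs or constant distances")
            report.excluded.append(name)
            continue
        r = float(corr_fn(p, c)[0])
        results[name] = {
            "correlation": r,
            "n_pairs": int(len(p)),
            "mean_p": float(p.mean()),
            "mean_corrected": float(c.mean()),
        }
    ranked = sorted(results, key=lambda n: results[n]["correlation"])
    bottom = set(ranked[:bottom_k]) if len(ranked) > bottom_k else set()
    for name, stats in results.items():
        stats["flagged"] = bool(stats["correlation"] < threshold or name in bottom)
    report.partitions = results
    return report
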