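"""Age-given-length model for IBD segments.

Longer IBD segments tend to descend from younger common ancestors (the
expected segment length given TMRCA ``t`` is 1/(2t) Morgans), but within a
length bin the age distribution is broad and multimodal under non-constant
demography.  Following visual adequacy, segment ages within each 0.1 cM
length bin are modelled as a two-component gamma mixture fitted by EM; the
fitted per-bin mixtures are then used to sample ages given (apparent)
lengths in the mutation-rate bias experiment.

The EM implementation: responsibilities in the E step; closed-form weight
and scale updates in the M step with the shape updated by Newton iterations
on the weighted digamma stationarity equation; initialisation splits the
data at the median (or a random quantile on restarts) with method-of-moments
fits per half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp, polygamma

from .true_ibd import _as_frame

__all__ = [
    "GammaMixture",
    "AgeLengthModel",
    "bin_segments_by_length",
    "fit_gamma_mixture",
    "build_age_length_model",
    "sample_age",
]


@dataclass
class GammaMixture:
    """A k-component gamma mixture over positive ages (generations)."""

    weights: np.ndarray
    shapes: np.ndarray
    scales: np.ndarray
    loglik: float = np.nan
    n_obs: int = 0
    converged: bool = True
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.shapes = np.atleast_1d(np.asarray(self.shapes, dtype=float))
        self.scales = np.atleast_1d(np.asarray(self.scales, dtype=float))
        if not (len(self.weights) == len(self.shapes) == len(self.scales)):
            raise ValueError("component vectors must have equal length")
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1) > 1e-9:
            raise ValueError("weights must be positive and sum to 1")
        if np.any(self.shapes <= 0) or np.any(self.scales <= 0):
            raise ValueError("shapes and scales must be positive")

    @property
    def k(self) -> int:
        return len(self.weights)

    def component_means(self) -> np.ndarray:
        return self.shapes * self.scales

    def mean(self) -> float:
        return float(self.weights @ self.component_means())

    def logpdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lp = _gamma_logpdf(x[:, None], self.shapes[None, :], self.scales[None, :])
        return logsumexp(lp + np.log(self.weights)[None, :], axis=1)

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def cdf(self, x) -> np.ndarray:
        from scipy.stats import gamma as gamma_dist

        x = np.atleast_1d(np.asarray(x, dtype=float))
        parts = [
            w * gamma_dist.cdf(x, a, scale=s)
            for w, a, s in zip(self.weights, self.shapes, self.scales)
        ]
        return np.sum(parts, axis=0)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(self.k, size=size, p=self.weights)
        return rng.gamma(self.shapes[comp], self.scales[comp])


def _gamma_logpdf(x, shape, scale):
    return (
        (shape - 1) * np.log(x)
        - x / scale
        - gammaln(shape)
        - shape * np.log(scale)
    )


def _weighted_gamma_mle(x, logx, w):
    """Weighted maximum-likelihood gamma fit (shape via Newton on digamma)."""
    wsum = w.sum()
    m = (w @ x) / wsum
    lbar = (w @ logx) / wsum
    s = np.log(m) - lbar
    if s <= 1e-12:
        # essentially degenerate (zero variance): very peaked gamma
        return 1e6, m / 1e6
    k = (3 - s + np.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)
    for _ in range(40):
        f = np.log(k) - digamma(k) - s
        fp = 1.0 / k - polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2
        if abs(k_new - k) < 1e-12 * k:
            k = k_new
            break
        k = k_new
    k = float(np.clip(k, 1e-3, 1e6))
    return k, m / k


def _moment_gamma(x):
    m = x.mean()
    v = x.var()
    if v <= 0:
        return 1e6, m / 1e6
    shape = m * m / v
    return float(np.clip(shape, 1e-3, 1e6)), m / np.clip(shape, 1e-3, 1e6)


def fit_gamma_mixture(
    ages,
    k: int = 2,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 5,
    rng: np.random.Generator | None = None,
) -> GammaMixture:
    """Fit a k-component gamma mixture to positive ages by EM.

    The best of ``n_restarts`` runs (by log-likelihood) is returned with
    components in ascending order of mean.  With fewer than ``10 * k``
    observations the fit falls back to a single method-of-moments gamma.
    """
    x = np.asarray(ages, dtype=float)
    if np.any(x <= 0):
        raise ValueError("ages must be strictly positive")
    if rng is None:
        rng = np.random.default_rng()
    if len(x) < 10 * k:
        warnings.warn(
            f"only {len(x)} observations; falling back to a single gamma fit"
        )
        shape, scale = _moment_gamma(x)
        gm = GammaMixture(
            weights=np.array([1.0]),
            shapes=np.array([shape]),
            scales=np.array([scale]),
            n_obs=len(x),
        )
        gm.loglik = float(gm.logpdf(x).sum())
        return gm
    logx = np.log(x)
    best: GammaMixture | None = None
    for restart in range(n_restarts):
        if restart == 0:
            qs = np.linspace(0, 1, k + 1)[1:-1]
        else:
            qs = np.sort(rng.uniform(0.15, 0.85, size=k - 1))
        cuts = np.quantile(x, qs)
        grp_idx = np.searchsorted(cuts, x)
        groups = [grp_idx == j for j in range(k)]
        weights = np.array([max(g.mean(), 1e-3) for g in groups])
        weights = weights / weights.sum()
        shapes = np.empty(k)
        scales = np.empty(k)
        for j, g in enumerate(groups):
            xs = x[g] if g.sum() >= 2 else x
            shapes[j], scales[j] = _moment_gamma(xs)
        ll_prev = -np.inf
        trace = []
        converged = False
        for _ in range(max_iter):
            lp = (
                _gamma_logpdf(x[:, None], shapes[None, :], scales[None, :])
                + np.log(weights)[None, :]
            )
            norm = logsumexp(lp, axis=1)
            ll = float(norm.sum())
            trace.append(ll)
            resp = np.exp(lp - norm[:, None])
            if ll - ll_prev < tol * abs(ll) and np.isfinite(ll_prev):
                converged = True
                break
            ll_prev = ll
            for j in range(k):
                w = resp[:, j]
                if w.sum() < 1e-8 * len(x):
                    # dead component: re-seed on a random data slice
                    idx = rng.integers(0, len(x), size=max(10, len(x) // 10))
                    shapes[j], scales[j] = _moment_gamma(x[idx])
                    weights[j] = 1.0 / len(x)
                    continue
                shapes[j], scales[j] = _weighted_gamma_mle(x, logx, w)
                weights[j] = w.sum() / len(x)
            weights = weights / weights.sum()
        order = np.argsort(shapes * scales)
        gm = GammaMixture(
            weights=weights[order],
            shapes=shapes[order],
            scales=scales[order],
            loglik=trace[-1],
            n_obs=len(x),
            converged=converged,
            loglik_trace=np.asarray(trace),
        )
        if best is None or gm.loglik > best.loglik:
            best = gm
    return best


def bin_segments_by_length(segments, bin_width_cm: float = 0.1) -> dict:
    """Group segment ages by half-open length bin ``[k*w, (k+1)*w)``.

    Returns a mapping from bin lower edge (rounded) to an array of ages.
    """
    frame = _as_frame(segments)
    lengths = frame["length_cm"].to_numpy(float)
    ages = frame["tmrca_gen"].to_numpy(float)
    if np.any(lengths <= 0) or np.any(ages <= 0):
        raise ValueError("segments must have positive lengths and ages")
    idx = np.floor(lengths / bin_width_cm + 1e-9).astype(int)
    out: dict[float, np.ndarray] = {}
    for b in np.unique(idx):
        out[round(b * bin_width_cm, 9)] = ages[idx == b]
    return out


@dataclass
class AgeLengthModel:
    """Per-length-bin gamma mixtures for IBD segment age given length.

    ``edges`` has one more entry than ``mixtures``; bin ``i`` spans
    ``[edges[i], edges[i+1])``.  Bins are contiguous; queries outside the
    modelled range are clamped to the nearest bin.
    """

    edges: np.ndarray
    mixtures: list[GammaMixture]
    bin_width_cm: float = 0.1

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if len(self.edges) != len(self.mixtures) + 1:
            raise ValueError("edges must bracket the mixtures")

    def bin_index(self, length_cm) -> np.ndarray:
        idx = np.searchsorted(self.edges, np.atleast_1d(length_cm), side="right") - 1
        return np.clip(idx, 0, len(self.mixtures) - 1)

    def mixture_for(self, length_cm: float) -> GammaMixture:
        return self.mixtures[int(self.bin_index(length_cm)[0])]

    def sample_ages(self, lengths_cm, rng: np.random.Generator) -> np.ndarray:
        """Vectorised age draws, one per entry of ``lengths_cm``."""
        lengths_cm = np.atleast_1d(np.asarray(lengths_cm, dtype=float))
        idx = self.bin_index(lengths_cm)
        out = np.empty(len(lengths_cm))
        for b in np.unique(idx):
            sel = idx == b
            out[sel] = self.mixtures[b].sample(int(sel.sum()), rng)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, gm in enumerate(self.mixtures):
            w = np.zeros(2)
            sh = np.zeros(2)
            sc = np.zeros(2)
            w[: gm.k] = gm.weights[:2]
            sh[: gm.k] = gm.shapes[:2]
            sc[: gm.k] = gm.scales[:2]
            if gm.k == 1:
                w = np.array([1.0, 0.0])
                sh = np.array([gm.shapes[0], np.nan])
                sc = np.array([gm.scales[0], np.nan])
            rows.append(
                (
                    self.edges[i],
                    self.edges[i + 1],
                    w[0],
                    sh[0],
                    sc[0],
                    w[1],
                    sh[1],
                    sc[1],
                    gm.n_obs,
                    gm.loglik,
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "bin_low_cm",
                "bin_high_cm",
                "w1",
                "shape1",
                "scale1",
                "w2",
                "shape2",
                "scale2",
                "n",
                "loglik",
            ],
        )

    def write_tsv(self, path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def read_tsv(cls, path) -> "AgeLengthModel":
        frame = pd.read_csv(path, sep="\t", comment="#")
        edges = np.append(
            frame["bin_low_cm"].to_numpy(), frame["bin_high_cm"].iloc[-1]
        )
        mixtures = []
        for r in frame.itertuples(index=False):
            if r.w2 > 0 and np.isfinite(r.shape2):
                gm = GammaMixture(
                    weights=np.array([r.w1, r.w2]) / (r.w1 + r.w2),
                    shapes=np.array([r.shape1, r.shape2]),
                    scales=np.array([r.scale1, r.scale2]),
                    loglik=r.loglik,
                    n_obs=int(r.n),
                )
            else:
                gm = GammaMixture(
                    weights=np.array([1.0]),
                    shapes=np.array([r.shape1]),
                    scales=np.array([r.scale1]),
                    loglik=r.loglik,
                    n_obs=int(r.n),
                )
            mixtures.append(gm)
        width = float(np.median(np.diff(edges)))
        return cls(edges=edges, mixtures=mixtures, bin_width_cm=width)


def build_age_length_model(
    segments,
    bin_width_cm: float = 0.1,
    min_count: int = 50,
    max_obs_per_fit: int = 5000,
    rng: np.random.Generator | None = None,
    **fit_kwargs,
) -> AgeLengthModel:
    """Fit one gamma mixture per sufficiently populated length bin.

    Bins with fewer than ``min_count`` segments are merged with the
    adjacent longer-length bin; a sparse trailing group is merged backward.
    Very large bins are fitted on a random subsample of
    ``max_obs_per_fit`` ages.
    """
    if rng is None:
        rng = np.random.default_rng()
    binned = bin_segments_by_length(segments, bin_width_cm)
    if not binned:
        raise ValueError("no segments to fit")
    lows = sorted(binned)
    # merge sparse bins into the adjacent longer-length group
    groups: list[tuple[float, float, np.ndarray]] = []
    acc: list[np.ndarray] = []
    acc_low = lows[0]
    for b in lows:
        acc.append(binned[b])
        total = sum(len(a) for a in acc)
        if total >= min_count:
            groups.append((acc_low, round(b + bin_width_cm, 9), np.concatenate(acc)))
            acc = []
            if b != lows[-1]:
                acc_low = round(b + bin_width_cm, 9)
    if acc:
        leftover = np.concatenate(acc)
        if groups:
            low, _, prev = groups[-1]
            groups[-1] = (low, round(lows[-1] + bin_width_cm, 9), np.concatenate([prev, leftover]))
        elif len(leftover) >= 10:
            groups.append((acc_low, round(lows[-1] + bin_width_cm, 9), leftover))
        else:
            raise ValueError("too few segments to fit any length bin")
    edges = [groups[0][0]] + [g[1] for g in groups]
    mixtures = []
    for _, _, ages in groups:
        if len(ages) > max_obs_per_fit:
            ages = rng.choice(ages, size=max_obs_per_fit, replace=False)
        mixtures.append(fit_gamma_mixture(ages, rng=rng, **fit_kwargs))
    return AgeLengthModel(edges=np.asarray(edges), mixtures=mixtures, bin_width_cm=bin_width_cm)


def sample_age(
    model: AgeLengthModel, length_cm: float, rng: np.random.Generator
) -> float:
    """Draw one age (generations) given a segment length, clamped to range."""
    return float(model.sample_ages([length_cm], rng)[0])
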