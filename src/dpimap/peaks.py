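"""Iterative GLR peak detection and maximum-likelihood peak refinement.

The model: every surviving TC site i at coordinate x_i contributes, per
replicate r, an independent binomial observation ``c_ir ~ Binomial(n_ir, p_i)``
where the per-site success probability is a flat background plus a sum of
Gaussian bumps in probability space::

    p_i = clip(b + sum_j A_j * exp(-(x_i - mu_j)^2 / (2 sigma_j^2)), eps, 1-eps)

Detection proceeds as sequential null-hypothesis testing: the current model
(initially background only) is challenged by a model with one additional
peak, fit by numerical maximum likelihood from a seed at the maximum of the
smoothed residual track.  The generalized likelihood-ratio statistic
``Lambda = 2 (logL1 - logL0)`` is compared against a null distribution; on
rejection the peak is absorbed (followed by a joint ML refinement of all
parameters) and the test repeats until a challenge fails.

Because the peak center is chosen by scanning, the usual chi-squared
asymptotics do not apply (boundary + selection effects); the default null is
therefore a parametric bootstrap of the scan statistic: background-only
datasets are simulated on the observed depths and the full scan-and-fit is
re-run on each, giving the distribution of the maximal Lambda under the
null.  A chi2(3) mode is available as a fast, anti-conservative alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .counts import FrequencyTrack, ReplicateSet, window_mean

__all__ = [
    "EmissionData",
    "GaussPeak",
    "PeakModelParams",
    "Peak",
    "PeakFit",
    "DetectionConfig",
    "NullCalibration",
    "PeakCallResult",
    "loglik",
    "fit_background",
    "fit_single_peak",
    "calibrate_null",
    "detect_peaks",
    "peaks_to_frame",
]


# --------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class EmissionData:
    """Per-site, per-replicate counts for one contig, positions increasing.

    ``n`` and ``c`` have shape (n_sites, n_replicates).  Because all
    replicates share the same success probability p_i, the likelihood depends
    on the counts only through the per-site totals, which are precomputed.
    """

    contig: str
    x: np.ndarray  # site positions, bp
    n: np.ndarray  # depths
    c: np.ndarray  # transition counts

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.int64)
        n = np.atleast_2d(np.asarray(self.n, dtype=np.int64))
        c = np.atleast_2d(np.asarray(self.c, dtype=np.int64))
        if n.shape != c.shape or n.shape[0] != x.shape[0]:
            raise ValueError("shape mismatch between x, n, c")
        if np.any(c > n) or np.any(c < 0):
            raise ValueError("need 0 <= c <= n")
        if np.any(np.diff(x) < 0):
            raise ValueError("positions must be sorted")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "_N", n.sum(axis=1))
        object.__setattr__(self, "_C", c.sum(axis=1))

    @property
    def N(self) -> np.ndarray:  # total depth per site
        return self._N

    @property
    def C(self) -> np.ndarray:  # total transition count per site
        return self._C

    @property
    def n_sites(self) -> int:
        return len(self.x)

    def log_binom_const(self) -> float:
        """Sum of log binomial coefficients over all sites and replicates."""
        cached = getattr(self, "_lbc", None)
        if cached is None:
            n, c = self.n, self.c
            cached = float(np.sum(gammaln(n + 1) - gammaln(c + 1) - gammaln(n - c + 1)))
            object.__setattr__(self, "_lbc", cached)
        return cached

    def pooled_freq(self) -> np.ndarray:
        return self.C / np.maximum(self.N, 1)

    @classmethod
    def from_replicates(
        cls, reps: ReplicateSet, track: FrequencyTrack | None = None,
        contig: str | None = None,
    ) -> "EmissionData":
        """Build emission data from (filtered) replicate tables.

        If ``track`` is given, only its surviving sites enter the model; the
        replicate tables supply the per-replicate counts at those sites.
        """
        keys, depth, alt = reps.wide()
        if track is not None:
            idx = pd.MultiIndex.from_frame(keys)
            want = pd.MultiIndex.from_frame(track.df[["contig", "pos", "strand"]])
            loc = idx.get_indexer(want)
            if np.any(loc < 0):
                raise ValueError("track contains sites absent from replicates")
            keys, depth, alt = keys.iloc[loc].reset_index(drop=True), depth[loc], alt[loc]
        contigs = keys["contig"].unique()
        if contig is None:
            if len(contigs) != 1:
                raise ValueError(
                    f"multiple contigs present ({list(contigs)}); pass contig="
                )
            contig = contigs[0]
        sel = (keys["contig"] == contig).to_numpy()
        keys, depth, alt = keys[sel], depth[sel], alt[sel]
        order = np.argsort(keys["pos"].to_numpy(), kind="stable")
        return cls(contig, keys["pos"].to_numpy()[order], depth[order], alt[order])


@dataclass(frozen=True)
class GaussPeak:
    mu: float
    A: float
    sigma: float


@dataclass(frozen=True)
class PeakModelParams:
    """Background rate plus localized Gaussian peaks (probability space)."""

    b: float
    peaks: tuple[GaussPeak, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.b < 1:
            raise ValueError("background rate must satisfy 0 <= b < 1")
        for pk in self.peaks:
            if pk.A < 0 or pk.sigma <= 0:
                raise ValueError("peaks need A >= 0 and sigma > 0")

    def gauss_sum(self, x: np.ndarray) -> np.ndarray:
        g = np.zeros(len(x))
        for pk in self.peaks:
            z = (x - pk.mu) / pk.sigma
            g += pk.A * np.exp(-0.5 * z * z)
        return g

    def rate(self, x: np.ndarray, eps: float = 1e-9) -> np.ndarray:
        """Clipped site success probabilities."""
        return np.clip(self.b + self.gauss_sum(np.asarray(x, dtype=float)),
                       eps, 1 - eps)


@dataclass(frozen=True)
class Peak:
    """One detected peak with its GLR statistic and p-value."""

    contig: str
    mu: float
    A: float
    sigma: float
    glr: float
    p_value: float
    n_sites_in_support: int


@dataclass(frozen=True)
class PeakFit:
    """Result of a single-peak ML fit (challenge model)."""

    mu: float
    A: float
    sigma: float
    b: float
    loglik: float  # includes binomial-coefficient constant
    ll_core: float  # without the constant (what Lambda is built from)
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class DetectionConfig:
    """Knobs of the detection procedure; defaults match the published scheme
    (95% confidence), with the bootstrap null as the honest default."""

    alpha: float = 0.05
    max_peaks: int = 50
    bootstrap_B: int = 199
    seed: int = 0
    sigma_min: float = 10.0
    sigma_max: float = 500.0
    epsilon: float = 1e-9
    calibration_mode: str = "bootstrap"  # or "chi2_df3"
    window_bp: int = 75
    restart_sigmas: tuple[float, ...] = (25.0, 75.0, 200.0)
    min_sites: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.bootstrap_B < 19:
            raise ValueError("bootstrap_B must be >= 19")
        if self.calibration_mode not in ("bootstrap", "chi2_df3"):
            raise ValueError(f"unknown calibration_mode {self.calibration_mode!r}")
        if self.calibration_mode == "bootstrap":
            k = int(np.ceil((1 - self.alpha) * (self.bootstrap_B + 1)))
            if k > self.bootstrap_B:
                raise ValueError(
                    f"bootstrap_B={self.bootstrap_B} too small for "
                    f"alpha={self.alpha}; need B >= (1-alpha)/alpha"
                )


# --------------------------------------------------------------------------
# likelihood


def _ll_core(p: np.ndarray, N: np.ndarray, C: np.ndarray) -> float:
    return float(C @ np.log(p) + (N - C) @ np.log1p(-p))


def loglik(data: EmissionData, params: PeakModelParams, eps: float = 1e-9) -> float:
    """Binomial log-likelihood of the data under ``params`` (PMF, with the
    binomial coefficients included)."""
    p = params.rate(data.x, eps)
    return _ll_core(p, data.N, data.C) + data.log_binom_const()


def fit_background(data: EmissionData) -> float:
    """Closed-form MLE of a constant deamination rate: total alt / total depth."""
    tot = data.N.sum()
    if tot == 0:
        raise ValueError("all depths are zero; background rate undefined")
    return float(data.C.sum() / tot)


# --------------------------------------------------------------------------
# single-peak fitting


def _nll_grad_single(theta, x, Cf, NmC, g0, eps):
    b, mu, A, sig = theta
    z = (x - mu) / sig
    g = A * np.exp(-0.5 * z * z)
    p_raw = b + g0 + g
    # fast path: no clipping needed (the overwhelmingly common case)
    if eps < p_raw.min() and p_raw.max() < 1 - eps:
        p = p_raw
        dldp = Cf / p - NmC / (1 - p)
    else:
        p = np.clip(p_raw, eps, 1 - eps)
        interior = (p_raw > eps) & (p_raw < 1 - eps)
        dldp = np.where(interior, Cf / p - NmC / (1 - p), 0.0)
    ll = Cf @ np.log(p) + NmC @ np.log1p(-p)
    gz = g * z
    db = dldp.sum()
    dmu = dldp @ gz / sig
    dA = dldp @ g / max(A, 1e-300)
    dsig = dldp @ (gz * z) / sig
    return -ll, -np.array([db, dmu, dA, dsig])


def _smoothed_residual(data: EmissionData, params: PeakModelParams,
                       cfg: DetectionConfig) -> np.ndarray:
    resid = data.pooled_freq() - params.rate(data.x, cfg.epsilon)
    return window_mean(data.x, resid, cfg.window_bp // 2)


def _fit_single_core(x, Cf, NmC, g0, b0, seed_pos, a0, cfg):
    """Restarted L-BFGS-B over (b, mu, A, sigma); returns the best result."""
    bounds = [
        (0.0, 1.0 - 1e-6),
        (float(x[0]), float(x[-1])),
        (1e-9, 1.0),
        (cfg.sigma_min, cfg.sigma_max),
    ]
    best = None
    any_ok = False
    messages = []
    for s0 in cfg.restart_sigmas:
        s0 = float(np.clip(s0, cfg.sigma_min, cfg.sigma_max))
        theta0 = np.array([b0, float(seed_pos), a0, s0])
        res = optimize.minimize(
            _nll_grad_single, theta0, args=(x, Cf, NmC, g0, cfg.epsilon),
            jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
        )
        any_ok = any_ok or res.success
        messages.append(str(res.message))
        if best is None or res.fun < best.fun:
            best = res
    return best, any_ok, messages


def fit_single_peak(
    data: EmissionData,
    current: PeakModelParams,
    seed_position: float,
    cfg: DetectionConfig | None = None,
) -> PeakFit:
    """ML fit of one additional Gaussian peak (existing peaks held fixed,
    background re-optimized), restarted from several widths.

    The center is initialized at ``seed_position``; the best of the restarts
    is returned.  Non-convergence of every restart is flagged on the result,
    not raised.
    """
    cfg = cfg or DetectionConfig()
    x = data.x.astype(float)
    if not (x.min() <= seed_position <= x.max()):
        raise ValueError("seed_position outside the contig's site span")
    Cf = data.C.astype(float)
    NmC = (data.N - data.C).astype(float)
    g0 = current.gauss_sum(x)
    resid = _smoothed_residual(data, current, cfg)
    i = min(int(np.searchsorted(x, seed_position)), len(x) - 1)
    a0 = min(float(max(resid[i], 1e-3)), 1.0)
    best, any_ok, messages = _fit_single_core(
        x, Cf, NmC, g0, current.b, seed_position, a0, cfg
    )
    b, mu, A, sig = best.x
    ll_core = -float(best.fun)
    return PeakFit(
        mu=float(mu), A=float(A), sigma=float(sig), b=float(b),
        loglik=ll_core + data.log_binom_const(), ll_core=ll_core,
        converged=any_ok, message="" if any_ok else "; ".join(messages),
    )


def _nll_grad_multi(theta, x, Cf, NmC, eps):
    K = (len(theta) - 1) // 3
    b = theta[0]
    p_raw = np.full(len(x), b)
    gs, zs, sigs = [], [], []
    for j in range(K):
        mu, A, sig = theta[1 + 3 * j : 4 + 3 * j]
        z = (x - mu) / sig
        g = A * np.exp(-0.5 * z * z)
        p_raw += g
        gs.append(g)
        zs.append(z)
        sigs.append((A, sig))
    p = np.clip(p_raw, eps, 1 - eps)
    ll = Cf @ np.log(p) + NmC @ np.log1p(-p)
    interior = (p_raw > eps) & (p_raw < 1 - eps)
    dldp = np.where(interior, Cf / p - NmC / (1 - p), 0.0)
    grad = np.empty(len(theta))
    grad[0] = dldp.sum()
    for j in range(K):
        g, z = gs[j], zs[j]
        A, sig = sigs[j]
        grad[1 + 3 * j] = dldp @ (g * z / sig)
        grad[2 + 3 * j] = dldp @ (g / max(A, 1e-300))
        grad[3 + 3 * j] = dldp @ (g * z * z / sig)
    return -ll, -grad


def _joint_refine(data: EmissionData, params: PeakModelParams,
                  cfg: DetectionConfig) -> tuple[PeakModelParams, float]:
    """Joint ML refinement of background and all peak parameters."""
    x = data.x.astype(float)
    theta0 = [params.b]
    bounds = [(0.0, 1.0 - 1e-6)]
    for pk in params.peaks:
        theta0 += [pk.mu, pk.A, pk.sigma]
        bounds += [
            (float(x.min()), float(x.max())),
            (1e-9, 1.0),
            (cfg.sigma_min, cfg.sigma_max),
        ]
    res = optimize.minimize(
        _nll_grad_multi, np.array(theta0),
        args=(x, data.C.astype(float), (data.N - data.C).astype(float), cfg.epsilon),
        jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 400, "ftol": 1e-12, "gtol": 1e-8},
    )
    th = res.x
    refined = PeakModelParams(
        b=float(th[0]),
        peaks=tuple(
            GaussPeak(float(th[1 + 3 * j]), float(th[2 + 3 * j]), float(th[3 + 3 * j]))
            for j in range(len(params.peaks))
        ),
    )
    return refined, -float(res.fun)


# --------------------------------------------------------------------------
# null calibration


@dataclass(frozen=True)
class NullCalibration:
    """Rejection threshold and p-value map for the scan GLR statistic."""

    mode: str
    alpha: float
    threshold: float
    null_stats: np.ndarray | None = None  # sorted ascending (bootstrap mode)

    def pvalue(self, lam: float) -> float:
        if self.mode == "chi2_df3":
            return float(stats.chi2.sf(lam, 3))
        B = len(self.null_stats)
        count = int(np.sum(self.null_stats >= lam))
        return (1 + count) / (B + 1)

    def reject(self, lam: float) -> bool:
        return self.pvalue(lam) <= self.alpha


def _scan_fit_lambda(x, N, C, cfg) -> float:
    """One scan-and-fit on (aggregated) counts; returns the GLR statistic of
    the first challenge peak against the flat-background null."""
    tot = N.sum()
    b0 = min(C.sum() / tot if tot else 0.0, 1 - 1e-9)
    Cf = C.astype(float)
    NmC = (N - C).astype(float)
    p0 = np.clip(b0, cfg.epsilon, 1 - cfg.epsilon)
    ll0 = float(Cf.sum() * np.log(p0) + NmC.sum() * np.log1p(-p0))
    resid = window_mean(x, C / np.maximum(N, 1) - p0, cfg.window_bp // 2)
    i = int(np.argmax(resid))
    a0 = min(float(max(resid[i], 1e-3)), 1.0)
    g0 = np.zeros(len(x))
    best, _, _ = _fit_single_core(x, Cf, NmC, g0, b0, float(x[i]), a0, cfg)
    return max(0.0, 2.0 * (-float(best.fun) - ll0))


def calibrate_null(
    data: EmissionData,
    b_hat: float,
    cfg: DetectionConfig,
    rng: np.random.Generator | None = None,
) -> NullCalibration:
    """Calibrate the rejection threshold for the scan GLR statistic.

    Bootstrap mode simulates ``bootstrap_B`` background-only datasets on the
    observed depth skeleton at rate ``b_hat``, reruns the scan-and-fit on
    each, and takes the ceil((1-alpha)(B+1))-th order statistic of the
    resulting max-GLR values as threshold; p-values use the +1-corrected
    empirical tail.  chi2_df3 mode uses the chi-squared(3) quantile, which
    ignores scan selection and is anti-conservative.
    """
    if cfg.calibration_mode == "chi2_df3":
        return NullCalibration("chi2_df3", cfg.alpha,
                               float(stats.chi2.ppf(1 - cfg.alpha, 3)))
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    x = data.x.astype(float)
    N = data.N
    lams = np.empty(cfg.bootstrap_B)
    for b_iter in range(cfg.bootstrap_B):
        Cb = rng.binomial(N, b_hat)
        lams[b_iter] = _scan_fit_lambda(x, N, Cb, cfg)
    lams.sort()
    k = int(np.ceil((1 - cfg.alpha) * (cfg.bootstrap_B + 1)))
    return NullCalibration("bootstrap", cfg.alpha, float(lams[k - 1]), lams)


# --------------------------------------------------------------------------
# iterative detection


@dataclass(frozen=True)
class PeakCallResult:
    """Peaks (sorted by GLR statistic, descending), the fitted model, and the
    calibration used."""

    contig: str
    peaks: tuple[Peak, ...]
    model: PeakModelParams
    calibration: NullCalibration
    config: DetectionConfig = field(default_factory=DetectionConfig)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def detect_peaks(data: EmissionData, cfg: DetectionConfig | None = None) -> PeakCallResult:
    """Greedy iterative GLR peak detection.

    Seeds each challenge peak at the maximum of the smoothed residual track
    (ties resolved leftmost by argmax), fits it by ML, and GLR-tests it
    against the current model; rejection of the null absorbs the peak
    (followed by joint refinement of all parameters) and the loop continues
    until a challenge is not rejected or ``max_peaks`` is reached.
    """
    cfg = cfg or DetectionConfig()
    empty_calib = NullCalibration("chi2_df3", cfg.alpha,
                                  float(stats.chi2.ppf(1 - cfg.alpha, 3)))
    if data.n_sites < cfg.min_sites or data.C.sum() == 0:
        warnings.warn(
            f"degenerate input on {data.contig!r} "
            f"({data.n_sites} sites, {int(data.C.sum())} alt reads); "
            "no peaks called"
        )
        b0 = 0.0 if data.N.sum() == 0 else fit_background(data)
        return PeakCallResult(data.contig, (), PeakModelParams(b=b0),
                              empty_calib, cfg)

    rng = np.random.default_rng(cfg.seed)
    b0 = fit_background(data)
    calib = calibrate_null(data, b0, cfg, rng)
    params = PeakModelParams(b=min(b0, 1 - 1e-9))
    x = data.x.astype(float)
    ll_cur = _ll_core(params.rate(x, cfg.epsilon), data.N, data.C)

    records: list[tuple[float, float]] = []  # (Lambda, p) in acceptance order
    while len(params.peaks) < cfg.max_peaks:
        resid = _smoothed_residual(data, params, cfg)
        seed = float(x[int(np.argmax(resid))])
        fit = fit_single_peak(data, params, seed, cfg)
        lam = max(0.0, 2.0 * (fit.ll_core - ll_cur))
        pval = calib.pvalue(lam)
        if pval > cfg.alpha:
            break
        params = PeakModelParams(
            b=fit.b,
            peaks=params.peaks + (GaussPeak(fit.mu, fit.A, fit.sigma),),
        )
        params, ll_cur = _joint_refine(data, params, cfg)
        records.append((lam, pval))

    peaks = []
    for (lam, pval), pk in zip(records, params.peaks):
        support = int(np.sum(np.abs(x - pk.mu) <= 2 * pk.sigma))
        peaks.append(Peak(data.contig, pk.mu, pk.A, pk.sigma, lam, pval, support))
    peaks.sort(key=lambda p: p.glr, reverse=True)
    return PeakCallResult(data.contig, tuple(peaks), params, calib, cfg)


def peaks_to_frame(result: PeakCallResult) -> pd.DataFrame:
    """Peak table with 1-based centers, ready for TSV export."""
    cfg = result.config
    rows = [
        {
            "contig": pk.contig,
            "center": int(round(pk.mu)) + 1,
            "amplitude": pk.A,
            "sigma_bp": pk.sigma,
            "glr_statistic": pk.glr,
            "p_value": pk.p_value,
            "n_sites": pk.n_sites_in_support,
            "alpha": cfg.alpha,
            "calibration_mode": cfg.calibration_mode,
            "seed": cfg.seed,
        }
        for pk in result.peaks
    ]
    cols = ["contig", "center", "amplitude", "sigma_bp", "glr_statistic",
            "p_value", "n_sites", "alpha", "calibration_mode", "seed"]
    return pd.DataFrame(rows, columns=cols)
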