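"""Coefficient of intrinsic dependence (CID) and partial CID (pCID).

The CID quantifies how strongly the conditional distribution of a response
gene Y shifts with a predictor gene X, by aggregating squared discrepancies
between the kernel-estimated conditional CDF and the marginal CDF::

    CID(Y|X) = (1/N) * sum_i sum_j [F(y_i | x_j) - F(y_i)]^2
                       / sum_i F(y_i) * (1 - F(y_i))

It is 0 under independence, 1 under full (functional, injective) dependence
in the empirical-CDF limit, and asymmetric in its arguments — the property
used downstream to orient regulatory edges.

The partial CID removes the share of the response distribution already
explained by a conditioning set X1 before crediting a new predictor X2::

    pCID(Y|X2; X1) = (CID(Y|X2,X1) - CID(Y|X1)) / (1 - CID(Y|X1))

Distribution functions are estimated by Gaussian kernel smoothing: an
integrated (CDF) kernel for the response and a product of Gaussian density
weights over the conditioning variables (a Nadaraya-Watson conditional CDF).
Setting ``degenerate_limit`` in :class:`KernelConfig` collapses both to
indicator-based empirical CDFs, which admit exact hand-computable values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "ExpressionMatrix",
    "KernelConfig",
    "DependenceResult",
    "estimate_marginal_cdf",
    "estimate_conditional_cdf",
    "cid",
    "pcid",
    "CIDEngine",
]

logger = logging.getLogger(__name__)

#: Smallest admissible denominator before raising instead of returning NaN.
DENOM_EPS = 1e-12

#: 1 - CID(Y|X1) below this is treated as a saturated conditioning set.
SATURATION_TOL = 1e-9

MIN_SAMPLES = 5


# ---------------------------------------------------------------------------
# Configuration and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelConfig:
    """Settings for the kernel CDF estimators.

    Parameters
    ----------
    kernel_family :
        Name of the smoothing kernel. Only the Gaussian integrated kernel
        (for the response CDF) with Gaussian density weights (for
        conditioning) is implemented.
    bandwidth_rule :
        Bandwidth selector name. ``"reference"`` (the default and only
        rule) uses the robust spread ``sigma = min(sd, IQR/1.349)`` with

        * response CDF kernel: ``h = 1.06 * sigma * N**(-1/5)`` (the
          univariate normal-reference rule), and
        * conditioning weights over ``d`` predictors:
          ``h_j = 1.474 * sigma_j * N**(-1/(4+d))`` — Terrell's
          maximal-smoothing constant ``3*(1/35)**(1/5)`` at the
          d-dimensional optimal rate. Oversmoothing the conditioning
          variables keeps the Nadaraya-Watson weights stable as the
          conditioning set grows; the permutation null absorbs the
          (common-mode) bias, so power is retained where a
          per-variable univariate rule degenerates.
    bandwidth_scale :
        Positive multiplier applied to every bandwidth.
    degenerate_limit :
        If true, use the bandwidth->0 limit: indicator (empirical) CDFs for
        the response and exact-match weights for conditioning. This mode has
        exact closed-form oracles and is used heavily in testing.
    """

    kernel_family: str = "gaussian"
    bandwidth_rule: str = "reference"
    bandwidth_scale: float = 1.0
    degenerate_limit: bool = False

    def __post_init__(self) -> None:
        if self.bandwidth_scale <= 0:
            raise ValueError("bandwidth_scale must be > 0")
        if self.kernel_family != "gaussian":
            raise ValueError(f"unknown kernel_family {self.kernel_family!r}")
        if self.bandwidth_rule != "reference":
            raise ValueError(f"unknown bandwidth_rule {self.bandwidth_rule!r}")


@dataclass(frozen=True)
class DependenceResult:
    """A CID or pCID statistic, optionally with its permutation p-value."""

    kind: str  # "CID" or "pCID"
    response: str
    predictors: tuple[str, ...]
    value: float
    conditioning: tuple[str, ...] = ()
    p_value: float | None = None
    n_perm: int | None = None

    def label(self) -> str:
        preds = ",".join(self.predictors)
        if self.kind == "pCID":
            cond = ",".join(self.conditioning)
            return f"pCID({self.response}|{preds}; {cond})"
        return f"CID({self.response}|{preds})"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = f"{self.label()} = {self.value:.4f}"
        if self.p_value is not None:
            s += f" (p = {self.p_value:.4f}, {self.n_perm} permutations)"
        return s


class ExpressionMatrix:
    """A probes x samples matrix of log2 expression values.

    Rows are probes (genes), columns are samples. Probe identifiers must be
    unique; rows containing missing values are dropped (with a logged count)
    because no statistic here tolerates missing observations.
    """

    def __init__(self, probe_ids: Sequence[str], sample_ids: Sequence[str],
                 values: np.ndarray):
        probe_ids = [str(p) for p in probe_ids]
        sample_ids = [str(s) for s in sample_ids]
        values = np.asarray(values, dtype=float)
        if values.shape != (len(probe_ids), len(sample_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(probe_ids)} probes x {len(sample_ids)} samples")
        if len(set(probe_ids)) != len(probe_ids):
            dupes = sorted({p for p in probe_ids if probe_ids.count(p) > 1})
            raise ValueError(f"duplicate probe ids: {dupes}")
        bad = np.isnan(values).any(axis=1)
        if bad.any():
            logger.warning("dropping %d probe(s) with missing values",
                           int(bad.sum()))
            warnings.warn(f"dropped {int(bad.sum())} probe(s) with missing "
                          "values", UserWarning, stacklevel=2)
            keep = ~bad
            probe_ids = [p for p, k in zip(probe_ids, keep) if k]
            values = values[keep]
        self.probe_ids = list(probe_ids)
        self.sample_ids = list(sample_ids)
        self.values = values
        self._index = {p: i for i, p in enumerate(self.probe_ids)}

    @property
    def N(self) -> int:
        """Number of samples."""
        return len(self.sample_ids)

    @property
    def G(self) -> int:
        """Number of probes."""
        return len(self.probe_ids)

    def row(self, probe: str) -> np.ndarray:
        try:
            return self.values[self._index[probe]]
        except KeyError:
            raise KeyError(f"unknown probe id {probe!r}") from None

    def rows(self, probes: Sequence[str]) -> np.ndarray:
        """Values for several probes, shape (len(probes), N)."""
        return np.vstack([self.row(p) for p in probes])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.index, df.columns, df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids,
                            columns=self.sample_ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix(G={self.G}, N={self.N})"


# ---------------------------------------------------------------------------
# Bandwidths and CDF estimators
# ---------------------------------------------------------------------------

#: Terrell's maximal-smoothing constant for the Gaussian kernel,
#: 3 * (1/35)**(1/5).
OVERSMOOTH_CONST = 3.0 * 35.0 ** (-0.2)


def _robust_sigma(v: np.ndarray) -> float:
    """min(sd, IQR/1.349); falls back to sd when the IQR is zero (ties)."""
    sd = float(np.std(v, ddof=1))
    q75, q25 = np.percentile(v, [75, 25])
    iqr_sigma = (q75 - q25) / 1.349
    return min(sd, iqr_sigma) if iqr_sigma > 0 else sd


def _response_bandwidth(v: np.ndarray, cfg: KernelConfig) -> float:
    """Univariate normal-reference rule for the response CDF kernel."""
    return 1.06 * _robust_sigma(v) * len(v) ** (-0.2) * cfg.bandwidth_scale


def _conditioning_bandwidth(v: np.ndarray, d: int,
                            cfg: KernelConfig) -> float:
    """Oversmoothed reference rule for one of ``d`` conditioning variables.

    h = 1.474 * sigma * N^(-1/(4+d)); see :class:`KernelConfig`.
    """
    rate = len(v) ** (-1.0 / (4.0 + d))
    return OVERSMOOTH_CONST * _robust_sigma(v) * rate * cfg.bandwidth_scale


def _check_response(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.size < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {y.size}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in response")
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: zero variance")
    return y


def _as_predictor_matrix(x: np.ndarray, n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != n:
        raise ValueError(f"predictor sample count {x.shape[0]} != {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in predictors")
    return x


def estimate_marginal_cdf(y: np.ndarray, eval_points: np.ndarray,
                          cfg: KernelConfig | None = None) -> np.ndarray:
    """Kernel-smoothed marginal CDF of ``y`` at ``eval_points``.

    With ``cfg.degenerate_limit`` this is the empirical CDF with <=
    counting. Nondecreasing over sorted ``eval_points`` and bounded in
    [0, 1] by construction.
    """
    cfg = cfg or KernelConfig()
    y = _check_response(y)
    e = np.asarray(eval_points, dtype=float).ravel()
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite evaluation points")
    h = 0.0 if cfg.degenerate_limit else _response_bandwidth(y, cfg)
    if h <= 0:
        return np.mean(y[None, :] <= e[:, None], axis=1)
    return np.mean(ndtr((e[:, None] - y[None, :]) / h), axis=1)


def _condition_weights(x: np.ndarray, eval_x: np.ndarray,
                       cfg: KernelConfig) -> np.ndarray:
    """Row-normalized conditioning weights, shape (q, N).

    Row j holds the weight of each training sample when conditioning at
    ``eval_x[j]``: a product of per-predictor Gaussian densities (or exact
    match indicators in the degenerate limit). A zero-variance predictor
    contributes uniform weights (it carries no information) with a warning.
    """
    n, d = x.shape
    q = eval_x.shape[0]
    if cfg.degenerate_limit:
        match = np.ones((q, n), dtype=bool)
        for c in range(d):
            match &= eval_x[:, c][:, None] == x[:, c][None, :]
        w = match.astype(float)
    else:
        logw = np.zeros((q, n))
        for c in range(d):
            h = _conditioning_bandwidth(x[:, c], d, cfg)
            if h <= 0:
                logger.warning("zero-variance predictor column %d: "
                               "contributes uniform weights", c)
                warnings.warn("zero-variance predictor: conditioning reduces "
                              "toward the marginal", UserWarning,
                              stacklevel=3)
                continue
            z = (eval_x[:, c][:, None] - x[:, c][None, :]) / h
            logw += -0.5 * z * z
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
    tot = w.sum(axis=1, keepdims=True)
    empty = tot[:, 0] <= 0
    if empty.any():
        # only reachable in the degenerate limit at unseen x values
        w[empty] = 1.0
        tot = w.sum(axis=1, keepdims=True)
    return w / tot


def estimate_conditional_cdf(y: np.ndarray, x: np.ndarray,
                             eval_y: np.ndarray, eval_x: np.ndarray,
                             cfg: KernelConfig | None = None) -> np.ndarray:
    """Nadaraya-Watson conditional CDF estimate F(y | x).

    Returns a matrix of shape ``(len(eval_y), len(eval_x))`` whose entry
    (i, j) estimates F(eval_y[i] | X = eval_x[j]). Multi-predictor
    conditioning uses a product Gaussian weighting with independent
    per-predictor bandwidths.
    """
    cfg = cfg or KernelConfig()
    y = _check_response(y)
    x = _as_predictor_matrix(x, y.size)
    eval_y = np.asarray(eval_y, dtype=float).ravel()
    eval_x = np.asarray(eval_x, dtype=float)
    if eval_x.ndim == 1:
        eval_x = eval_x[:, None]
    if eval_x.shape[1] != x.shape[1]:
        raise ValueError("eval_x predictor count differs from x")
    h = 0.0 if cfg.degenerate_limit else _response_bandwidth(y, cfg)
    if h <= 0:
        kern = (y[None, :] <= eval_y[:, None]).astype(float)  # (m, N)
    else:
        kern = ndtr((eval_y[:, None] - y[None, :]) / h)
    w = _condition_weights(x, eval_x, cfg)  # (q, N)
    return kern @ w.T


# ---------------------------------------------------------------------------
# CID / pCID statistics
# ---------------------------------------------------------------------------

@dataclass
class _ResponseTerms:
    """Precomputed response-side quantities for fast (permuted) CID sums.

    For a permutation ``p`` of the response, the CID numerator is

        sum_{k,l} V[k,l] * M[p_k, p_l]  -  2 * sum_k c[k] * g[p_k]
                                        +  N * sum(Fm^2)

    with ``M = K.T @ K`` and ``g = K.T @ Fm`` fixed, and ``V = W.T @ W``,
    ``c = W.sum(0)`` depending only on the (unpermuted) predictors. The
    denominator sum(Fm * (1 - Fm)) is permutation-invariant.
    """

    K: np.ndarray          # (N, N) response CDF kernel, K[i, k] = k_h(y_i - y_k)
    Fm: np.ndarray         # marginal CDF at the sample points
    M: np.ndarray          # K.T @ K
    g: np.ndarray          # K.T @ Fm
    den: float             # sum Fm (1 - Fm)
    sum_fm2: float         # sum Fm^2
    N: int = field(init=False)

    def __post_init__(self) -> None:
        self.N = self.Fm.size


def _response_terms(y: np.ndarray, cfg: KernelConfig) -> _ResponseTerms:
    y = _check_response(y)
    h = 0.0 if cfg.degenerate_limit else _response_bandwidth(y, cfg)
    if h <= 0:
        K = (y[None, :] <= y[:, None]).astype(float)
    else:
        K = ndtr((y[:, None] - y[None, :]) / h)
    Fm = K.mean(axis=1)
    den = float(np.sum(Fm * (1.0 - Fm)))
    if den < DENOM_EPS:
        raise ValueError("degenerate response: CID denominator is zero")
    return _ResponseTerms(K=K, Fm=Fm, M=K.T @ K, g=K.T @ Fm, den=den,
                          sum_fm2=float(np.sum(Fm ** 2)))


def _predictor_terms(x: np.ndarray, cfg: KernelConfig
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(V, c) for conditioning at the sample points themselves."""
    w = _condition_weights(x, x, cfg)
    return w.T @ w, w.sum(axis=0)


def _cid_from_gathered(rt: _ResponseTerms, V: np.ndarray, c: np.ndarray,
                       Mp: np.ndarray, gp: np.ndarray) -> float:
    num = float(np.vdot(V, Mp)) - 2.0 * float(c @ gp) + rt.N * rt.sum_fm2
    return max(num, 0.0) / (rt.N * rt.den)


def _cid_value(rt: _ResponseTerms, V: np.ndarray, c: np.ndarray,
               perm: np.ndarray | None = None) -> float:
    if perm is None:
        Mp, gp = rt.M, rt.g
    else:
        Mp = rt.M[np.ix_(perm, perm)]
        gp = rt.g[perm]
    return _cid_from_gathered(rt, V, c, Mp, gp)


def cid(y: np.ndarray, X: np.ndarray, cfg: KernelConfig | None = None,
        response: str = "Y",
        predictors: Sequence[str] | None = None) -> DependenceResult:
    """CID(Y | X), with X one or several (joint) predictors.

    ``X`` of shape (N,) or (N, d); d > 1 gives the joint multi-predictor
    CID used by the pCID recursion.
    """
    cfg = cfg or KernelConfig()
    y = _check_response(y)
    x = _as_predictor_matrix(X, y.size)
    rt = _response_terms(y, cfg)
    V, c = _predictor_terms(x, cfg)
    if predictors is None:
        predictors = tuple(f"X{i + 1}" for i in range(x.shape[1]))
    return DependenceResult(kind="CID", response=response,
                            predictors=tuple(predictors),
                            value=_cid_value(rt, V, c))


def pcid(y: np.ndarray, x2: np.ndarray, x1set: np.ndarray,
         cfg: KernelConfig | None = None, response: str = "Y",
         predictor: str = "X2",
         conditioning: Sequence[str] | None = None) -> DependenceResult:
    """pCID(Y | X2; X1set) by the recursive two-CID formula.

    May be negative; raises if the conditioning set already saturates the
    response (CID(Y|X1set) within ``SATURATION_TOL`` of 1).
    """
    cfg = cfg or KernelConfig()
    y = _check_response(y)
    x1 = _as_predictor_matrix(x1set, y.size)
    x2 = _as_predictor_matrix(x2, y.size)
    if x2.shape[1] != 1:
        raise ValueError("x2 must be a single predictor vector")
    rt = _response_terms(y, cfg)
    V1, c1 = _predictor_terms(x1, cfg)
    base = _cid_value(rt, V1, c1)
    if 1.0 - base <= SATURATION_TOL:
        raise ValueError("saturated conditioning set: CID(Y|X1) ~= 1")
    Vj, cj = _predictor_terms(np.hstack([x2, x1]), cfg)
    joint = _cid_value(rt, Vj, cj)
    if conditioning is None:
        conditioning = tuple(f"X1_{i + 1}" for i in range(x1.shape[1]))
    return DependenceResult(kind="pCID", response=response,
                            predictors=(predictor,),
                            conditioning=tuple(conditioning),
                            value=(joint - base) / (1.0 - base))


# ---------------------------------------------------------------------------
# Engine: cached evaluation over an ExpressionMatrix
# ---------------------------------------------------------------------------

class CIDEngine:
    """Evaluates CID/pCID statistics over a fixed expression matrix.

    Caches the response-side kernel quantities per probe and the
    predictor-side weight products per predictor set, so that the O(N^2)
    permutation fast path (see :class:`_ResponseTerms`) makes network
    construction with 10^2-10^3 permutations per test tractable.
    """

    def __init__(self, matrix: ExpressionMatrix,
                 cfg: KernelConfig | None = None):
        if matrix.N < MIN_SAMPLES:
            raise ValueError(f"need at least {MIN_SAMPLES} samples")
        self.matrix = matrix
        self.cfg = cfg or KernelConfig()
        self._resp: dict[str, _ResponseTerms] = {}
        self._pred: dict[tuple[str, ...], tuple[np.ndarray, np.ndarray]] = {}

    def response_terms(self, probe: str) -> _ResponseTerms:
        if probe not in self._resp:
            self._resp[probe] = _response_terms(self.matrix.row(probe),
                                                self.cfg)
        return self._resp[probe]

    def predictor_terms(self, probes: Sequence[str]
                        ) -> tuple[np.ndarray, np.ndarray]:
        # product weights are order-invariant; key on the sorted set
        key = tuple(sorted(probes))
        if key not in self._pred:
            x = self.matrix.rows(key).T
            self._pred[key] = _predictor_terms(x, self.cfg)
        return self._pred[key]

    def cid_value(self, response: str, predictors: Sequence[str] | str,
                  perm: np.ndarray | None = None) -> float:
        if isinstance(predictors, str):
            predictors = (predictors,)
        if response in predictors:
            raise ValueError("response must be distinct from predictors")
        rt = self.response_terms(response)
        V, c = self.predictor_terms(predictors)
        return _cid_value(rt, V, c, perm)

    def pcid_value(self, response: str, predictor: str,
                   conditioning: Sequence[str],
                   perm: np.ndarray | None = None) -> float:
        if not conditioning:
            raise ValueError("conditioning set must be nonempty")
        if response == predictor or response in conditioning:
            raise ValueError("response must be distinct from predictors")
        rt = self.response_terms(response)
        V1, c1 = self.predictor_terms(tuple(conditioning))
        Vj, cj = self.predictor_terms((predictor, *conditioning))
        if perm is None:
            Mp, gp = rt.M, rt.g
        else:
            Mp = rt.M[np.ix_(perm, perm)]
            gp = rt.g[perm]
        base = _cid_from_gathered(rt, V1, c1, Mp, gp)
        if 1.0 - base <= SATURATION_TOL:
            raise ValueError("saturated conditioning set: CID(Y|X1) ~= 1")
        joint = _cid_from_gathered(rt, Vj, cj, Mp, gp)
        return (joint - base) / (1.0 - base)

    def evaluate(self, kind: str, response: str,
                 predictor: str | Sequence[str],
                 conditioning: Sequence[str] = (),
                 perm: np.ndarray | None = None) -> float:
        """Dispatch on kind ("CID" or "pCID"), with optional permutation."""
        if kind == "CID":
            return self.cid_value(response, predictor, perm)
        if kind == "pCID":
            if not isinstance(predictor, str):
                (predictor,) = predictor
            return self.pcid_value(response, predictor, conditioning, perm)
        raise ValueError(f"unknown statistic kind {kind!r}")
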