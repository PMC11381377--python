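r"""Riemannian-aligned CSP + LDA decoding.

The decoder is trained on the epoched calibration trials that survived
blink gating and artifact rejection:

* **Trial covariance.**  For a 512 x 21 epoch ``X`` (channels as
  columns), ``P = Xc' Xc / (Nt - 1) + ridge * I`` with ``Xc`` the
  per-channel mean-removed samples.  The small ridge (1e-8 x mean
  diagonal by default) keeps ``P`` positive definite even with linearly
  dependent channels.

* **Riemannian alignment (RA).**  Per calibration run, the Karcher mean
  ``M_R = argmin_M sum_i || log(P_i^{-1} M) ||_F^2`` of the run's trial
  covariances is computed under the affine-invariant metric, and every
  trial is recentred as ``X~ = X M_R^{-1/2}``.  After alignment the
  run's covariance mean is (approximately) the identity, which removes
  inter-run shifts before spatial filtering.  The mean is found by the
  standard fixed-point iteration
  ``M <- M^{1/2} exp( mean_i log(M^{-1/2} P_i M^{-1/2}) ) M^{1/2}``,
  initialised at the arithmetic mean.

* **CSP.**  With class-average aligned covariances ``P1`` (right hand)
  and ``P2`` (left hand), the projection solves the generalized
  eigenproblem ``P1 w = lambda P2 w`` (equivalently, extremises the
  Rayleigh quotient ``w'P1w / w'P2w``); rows of ``Wp`` are eigenvectors
  sorted by descending eigenvalue and scaled so ``w'(P1+P2)w = 1``.  The
  spatial filters ``Ws`` are the first and last ``m`` rows (m = 3 →
  six filters): the first maximise class-1 variance, the last class-2
  variance.  Each filter's sign is fixed by making its
  largest-magnitude coefficient positive so exported topographies are
  reproducible.

* **Features and LDA.**  Each trial maps to the 6-vector of
  log-variances of its filter projections.  The LDA weight is
  ``w = ((cov F1 + cov F2)/2)^{-1} (mean F1 - mean F2)`` with bias
  ``b = -1/2 (mean F1 + mean F2) . w``; a trial is classed 1 (right) if
  ``w.F + b >= 0`` else 2 (ties go to class 1: the sign of an exactly
  zero decision value is a documented convention, not physiology).

For testing trials the same filter + epoch chain runs, the trial is
aligned with the Karcher mean of *all* training-trial covariances (not a
mean of per-run means), projected, and classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .core import CLASS_LEFT, CLASS_RIGHT, EpochedTrial, class_name
from .preprocess import FilterSpec, extract_epoch, filter_trial

__all__ = [
    "trial_covariance",
    "riemannian_mean",
    "invsqrtm",
    "align_trial",
    "align_runs",
    "csp_fit",
    "csp_features",
    "lda_fit",
    "SpatialModel",
    "LinearClassifier",
    "DecoderBundle",
    "DecodeResult",
    "fit_decoder",
    "decode_trial",
]


def trial_covariance(samples: np.ndarray, ridge: float | None = None,
                     trace_norm: bool = False) -> np.ndarray:
    """Ridge-regularized sample covariance of one epoch (channels as columns).

    ``trace_norm=True`` divides by the trace before the ridge, making the
    alignment insensitive to per-trial amplitude scale (off by default).
    """
    x = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    xc = x - x.mean(axis=0, keepdims=True)
    p = xc.T @ xc / (x.shape[0] - 1)
    if trace_norm:
        p = p / np.trace(p)
    if ridge is None:
        ridge = 1e-8 * float(np.mean(np.diag(p)))
    return p + ridge * np.eye(p.shape[0])


def _eigh_fun(m: np.ndarray, fun) -> np.ndarray:
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    return (v * fun(w)) @ v.T


def sqrtm(m: np.ndarray) -> np.ndarray:
    return _eigh_fun(m, np.sqrt)


def invsqrtm(m: np.ndarray) -> np.ndarray:
    return _eigh_fun(m, lambda w: 1.0 / np.sqrt(w))


def logm(m: np.ndarray) -> np.ndarray:
    return _eigh_fun(m, np.log)


def expm(m: np.ndarray) -> np.ndarray:
    return _eigh_fun(m, np.exp)


def _check_spd(m: np.ndarray) -> None:
    if not np.allclose(m, m.T, atol=1e-10 * max(1.0, np.abs(m).max())):
        raise ValueError("matrix is not symmetric")
    if np.linalg.eigvalsh((m + m.T) / 2.0).min() <= 0:
        raise ValueError("matrix is not positive definite")


def riemannian_mean(mats, tol: float = 1e-9, max_iter: int = 50) -> np.ndarray:
    """Karcher mean of SPD matrices under the affine-invariant metric.

    Gradient-descent fixed point initialised at the arithmetic mean: each
    step maps the matrices to the tangent space at the current iterate,
    averages, and retracts with an adaptive step size (shrunk whenever the
    gradient norm stops decreasing, the usual safeguard for dispersed
    inputs).  Stops when the tangent-space gradient norm drops below
    ``tol``; if ``max_iter`` is exhausted the last iterate is returned and
    a ``RuntimeWarning`` is emitted.
    """
    mats = [np.asarray(p, dtype=float) for p in mats]
    if not mats:
        raise ValueError("empty set of matrices")
    for p in mats:
        _check_spd(p)
    if len(mats) == 1:
        return mats[0].copy()
    m = np.mean(mats, axis=0)
    step = 1.0
    prev_norm = np.inf
    for _ in range(max_iter):
        m_isqrt = invsqrtm(m)
        m_sqrt = sqrtm(m)
        tangent = np.mean([logm(m_isqrt @ p @ m_isqrt) for p in mats], axis=0)
        norm = np.linalg.norm(tangent, "fro")
        if norm < tol:
            return m
        if norm < prev_norm:
            step = min(2.0, step * 1.1)
        else:
            step *= 0.5
        prev_norm = norm
        m = m_sqrt @ expm(step * tangent) @ m_sqrt
    import warnings
    warnings.warn("Riemannian mean did not converge; returning last iterate",
                  RuntimeWarning)
    return m


def align_trial(samples: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Recentre one trial: right-multiply by the mean's inverse square root."""
    x = np.asarray(samples, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if x.shape[1] != mean.shape[0]:
        raise ValueError("channel count does not match the alignment mean")
    return x @ invsqrtm(mean)


def align_runs(runs: list[list[EpochedTrial]], trace_norm: bool = False):
    """Riemannian-align every calibration run in place of its own mean.

    Returns ``(aligned_trials, labels, run_means)`` with trials pooled
    across runs in order.  Alignment uses no labels, so it can safely be
    applied before any cross-validation split.
    """
    aligned, labels, run_means = [], [], []
    for run in runs:
        covs = [trial_covariance(t.samples, trace_norm=trace_norm) for t in run]
        mr = riemannian_mean(covs, max_iter=200)
        run_means.append(mr)
        w = invsqrtm(mr)
        for t in run:
            aligned.append(EpochedTrial(samples=t.samples @ w, label=t.label,
                                        satisfied=t.satisfied,
                                        trial_id=t.trial_id, run_id=t.run_id))
            labels.append(t.label)
    return aligned, np.asarray(labels), run_means


@dataclass
class SpatialModel:
    """CSP projection fitted on Riemannian-aligned trials."""

    projection: np.ndarray          # Wp, full C x C, rows = filters
    filters: np.ndarray             # Ws, 2m x C
    eigenvalues: np.ndarray
    m_per_side: int = 3
    run_means: list = field(default_factory=list)
    global_mean: np.ndarray = None


@dataclass
class LinearClassifier:
    weight: np.ndarray
    bias: float

    def decision(self, features: np.ndarray) -> float:
        return float(np.dot(self.weight, np.asarray(features, dtype=float)) + self.bias)

    def predict(self, features: np.ndarray) -> int:
        return CLASS_RIGHT if self.decision(features) >= 0.0 else CLASS_LEFT


def csp_fit(trials: list[EpochedTrial], m_per_side: int = 3) -> SpatialModel:
    """Fit CSP filters on (aligned) epoched trials of both classes."""
    labels = np.array([t.label for t in trials])
    if not (np.any(labels == CLASS_RIGHT) and np.any(labels == CLASS_LEFT)):
        raise ValueError("both classes must be present")
    n_ch = trials[0].samples.shape[1]
    if n_ch < 2 * m_per_side:
        raise ValueError("need at least 2*m_per_side channels")
    covs = np.stack([trial_covariance(t.samples) for t in trials])
    p1 = covs[labels == CLASS_RIGHT].mean(axis=0)
    p2 = covs[labels == CLASS_LEFT].mean(axis=0)

    evals, evecs = linalg.eigh(p1, p2)      # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    w = evecs[:, order].T                    # rows are filters
    # scale: w (P1 + P2) w' = 1 per row, then make the largest coefficient positive
    for i in range(w.shape[0]):
        scale = float(w[i] @ (p1 + p2) @ w[i])
        w[i] /= np.sqrt(scale)
        if w[i][np.argmax(np.abs(w[i]))] < 0:
            w[i] = -w[i]
    ws = np.vstack([w[:m_per_side], w[-m_per_side:]])
    return SpatialModel(projection=w, filters=ws, eigenvalues=evals,
                        m_per_side=m_per_side)


def csp_features(samples: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Log-variance of the trial projected onto each spatial filter."""
    proj = np.asarray(samples, dtype=float) @ np.asarray(filters, dtype=float).T
    var = np.var(proj, axis=0, ddof=1)
    if np.any(var <= 0):
        raise ValueError("zero-variance projection")
    return np.log(var)


def lda_fit(features: np.ndarray, labels: np.ndarray,
            ridge: float = 1e-8) -> LinearClassifier:
    """Two-class LDA with the unweighted average of class covariances."""
    f = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    f1 = f[labels == CLASS_RIGHT]
    f2 = f[labels == CLASS_LEFT]
    if len(f1) < 2 or len(f2) < 2:
        raise ValueError("need at least two samples per class")
    m1, m2 = f1.mean(axis=0), f2.mean(axis=0)
    pooled = (np.cov(f1, rowvar=False) + np.cov(f2, rowvar=False)) / 2.0
    pooled = np.atleast_2d(pooled) + ridge * np.eye(f.shape[1])
    w = np.linalg.solve(pooled, m1 - m2)
    b = -0.5 * float((m1 + m2) @ w)
    return LinearClassifier(weight=w, bias=b)


@dataclass
class DecoderBundle:
    """Everything needed to decode a raw testing trial."""

    spatial: SpatialModel
    lda: LinearClassifier
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    window_s: tuple = (0.5, 2.5)


@dataclass
class DecodeResult:
    label: int
    command: str
    decision_value: float


def fit_decoder(runs: list[list[EpochedTrial]], m_per_side: int = 3,
                filter_spec: FilterSpec | None = None,
                window_s: tuple = (0.5, 2.5)) -> DecoderBundle:
    """Train the full decoder on per-run trial lists (already epoched and
    cleaned): per-run RA, pooled CSP, log-variance features, LDA.

    The bundle's ``global_mean`` — used to align testing trials — is the
    Karcher mean of all training trials' covariances pooled across runs.
    """
    aligned, labels, run_means = align_runs(runs)
    spatial = csp_fit(aligned, m_per_side=m_per_side)
    spatial.run_means = run_means
    all_covs = [trial_covariance(t.samples) for run in runs for t in run]
    spatial.global_mean = riemannian_mean(all_covs, max_iter=200)
    feats = np.stack([csp_features(t.samples, spatial.filters) for t in aligned])
    lda = lda_fit(feats, labels)
    return DecoderBundle(spatial=spatial, lda=lda,
                         filter_spec=filter_spec or FilterSpec(),
                         window_s=window_s)


def bundle_to_dict(bundle: DecoderBundle) -> dict:
    """JSON-serializable form of a trained bundle (matrices row-major)."""
    from dataclasses import asdict

    s = bundle.spatial
    return {
        "projection": s.projection.tolist(),
        "filters": s.filters.tolist(),
        "eigenvalues": s.eigenvalues.tolist(),
        "m_per_side": s.m_per_side,
        "run_means": [m.tolist() for m in s.run_means],
        "global_mean": s.global_mean.tolist(),
        "lda": {"weight": bundle.lda.weight.tolist(), "bias": bundle.lda.bias},
        "filter_spec": asdict(bundle.filter_spec),
        "window_s": list(bundle.window_s),
    }


def bundle_from_dict(d: dict) -> DecoderBundle:
    spec_kwargs = dict(d["filter_spec"])
    for key in ("bandpass_hz", "notch_hz"):
        spec_kwargs[key] = tuple(spec_kwargs[key])
    spatial = SpatialModel(
        projection=np.asarray(d["projection"]),
        filters=np.asarray(d["filters"]),
        eigenvalues=np.asarray(d["eigenvalues"]),
        m_per_side=int(d["m_per_side"]),
        run_means=[np.asarray(m) for m in d["run_means"]],
        global_mean=np.asarray(d["global_mean"]))
    lda = LinearClassifier(weight=np.asarray(d["lda"]["weight"]),
                           bias=float(d["lda"]["bias"]))
    return DecoderBundle(spatial=spatial, lda=lda,
                         filter_spec=FilterSpec(**spec_kwargs),
                         window_s=tuple(d["window_s"]))


def filter_topographies(bundle: DecoderBundle, montage=None) -> list[dict]:
    """Plot-ready (electrode, weight) tables for each spatial filter."""
    from .core import standard_montage

    montage = montage or standard_montage()
    coords = montage.coordinates()
    out = []
    for i, row in enumerate(bundle.spatial.filters):
        out.append({"filter": i,
                    "weights": [{"electrode": lab, "x": coords[lab][0],
                                 "y": coords[lab][1], "weight": float(w)}
                                for lab, w in zip(montage.all_labels, row)]})
    return out


def decode_trial(mi_samples: np.ndarray, bundle: DecoderBundle) -> DecodeResult:
    """Decode one raw 4-s testing trial into a movement command.

    Chain: band-pass + notch filter, epoch to the training window, align
    with the global training mean, project onto the CSP filters, classify
    with LDA.  Class 1 drives "right", class 2 "left".
    """
    if bundle.spatial.global_mean is None:
        raise ValueError("bundle has no global alignment mean (untrained?)")
    filtered = filter_trial(mi_samples, bundle.filter_spec)
    epoch = extract_epoch(filtered, bundle.window_s,
                          bundle.filter_spec.sampling_rate)
    aligned = align_trial(epoch, bundle.spatial.global_mean)
    feats = csp_features(aligned, bundle.spatial.filters)
    value = bundle.lda.decision(feats)
    label = CLASS_RIGHT if value >= 0.0 else CLASS_LEFT
    return DecodeResult(label=label,
                        command="right" if label == CLASS_RIGHT else "left",
                        decision_value=value)
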