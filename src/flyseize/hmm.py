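"""Three-state hidden-Markov behavioral classifier.

The classifier labels each video frame of an open-field trajectory as
``walking``, ``pausing`` or ``immobilized``:

1. *Windowing* — the x-y trajectory is split into 2-s windows (non-overlapping
   for training, stride 1 for frame-wise decoding).
2. *Features* — each window is rigidly aligned (translated to its centroid,
   rotated so its own first principal axis lies along +x with net displacement
   pointing in +x) and projected onto a dataset-level principal-component basis
   with per-component unit-variance scaling.
3. *HMM* — a 3-state Gaussian hidden Markov model is trained by Baum-Welch
   with multiple seeded restarts; states are labeled post hoc by a kinematic
   rule (largest expected within-window path length -> walking; of the two
   low-motion states the stickier one -> immobilized).
4. *Decoding* — forward-backward posteriors over stride-1 sliding windows give
   each frame a label (max-posterior state of its centred window) and a
   confidence in [0, 1] (that posterior).

Immobilization is the seizure-associated state: prolonged near-zero locomotion
with residual twitching, distinct from brief pauses mainly through dwell time
and jitter amplitude.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from hmmlearn.hmm import GaussianHMM
from hmmlearn.base import ConvergenceMonitor
from sklearn.decomposition import PCA

from .arena import AnalysisInterval
from .trajectory import Trajectory

__all__ = [
    "STATES", "TrajectoryWindow", "FeatureModel", "HmmModel", "StateSequence",
    "ImmobilizationSummary", "segment_windows", "align_windows",
    "fit_feature_model", "window_features", "window_path_lengths",
    "window_displacements", "kinematic_init",
    "train_classifier", "assign_state_labels", "decode_states", "viterbi_path",
    "immobilization_summary", "cumulative_onset_curve",
    "train_behavior_classifier", "save_model", "load_model",
]

logger = logging.getLogger(__name__)

#: canonical state order used for all decoded output
STATES: Tuple[str, str, str] = ("walking", "pausing", "immobilized")

MODEL_FORMAT = "flyseize-hmc"
MODEL_VERSION = 1


# ---------------------------------------------------------------------------
# windows and alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryWindow:
    """One fixed-length window of a trajectory (W frames x 2 coordinates)."""

    fly_id: str
    start_frame: int
    xy: np.ndarray
    interp_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.xy.ndim != 2 or self.xy.shape[1] != 2 or self.xy.shape[0] < 2:
            raise ValueError("window must be a (W, 2) array with W >= 2")


def segment_windows(
    traj: Trajectory,
    window_s: float = 2.0,
    stride_frames: Optional[int] = None,
    max_interp_fraction: float = 0.25,
) -> List[TrajectoryWindow]:
    """Split a trajectory into windows of ``window_s`` seconds.

    ``stride_frames`` defaults to the window length (sequential,
    non-overlapping — the training layout); pass 1 for the sliding windows
    used in frame-wise decoding.  Windows with more than
    ``max_interp_fraction`` interpolated frames are dropped with a log entry.
    """
    W = int(round(window_s * traj.fps))
    if len(traj) < W:
        raise ValueError(f"trajectory shorter than one {window_s}-s window")
    if stride_frames is None:
        stride_frames = W
    if stride_frames < 1:
        raise ValueError("stride_frames must be >= 1")
    xy = traj.xy
    out: List[TrajectoryWindow] = []
    dropped = 0
    for start in range(0, len(traj) - W + 1, stride_frames):
        frac = float(traj.gap_mask[start:start + W].mean())
        if frac > max_interp_fraction:
            dropped += 1
            continue
        out.append(TrajectoryWindow(traj.fly_id, start, xy[start:start + W], frac))
    if dropped:
        logger.info("fly %s: dropped %d windows over the interpolation limit",
                    traj.fly_id, dropped)
    return out


def align_windows(xy_stack: np.ndarray) -> np.ndarray:
    """Rigidly align a stack of windows, vectorized.

    Each (W, 2) window is translated to its centroid and rotated so its own
    first principal axis lies along +x, with the rotation's 180-degree
    ambiguity fixed so the net displacement has non-negative x.  A window with
    zero net displacement (e.g. a closed loop) keeps the raw principal-axis
    orientation — a documented tie-break.  Pure rotations only: mirror-image
    paths map to mirror-image aligned windows.
    """
    xy = np.asarray(xy_stack, float)
    single = xy.ndim == 2
    if single:
        xy = xy[None]
    c = xy - xy.mean(axis=1, keepdims=True)
    sxx = np.mean(c[:, :, 0] ** 2, axis=1)
    syy = np.mean(c[:, :, 1] ** 2, axis=1)
    sxy = np.mean(c[:, :, 0] * c[:, :, 1], axis=1)
    theta = 0.5 * np.arctan2(2.0 * sxy, sxx - syy)  # principal-axis angle
    ct, st = np.cos(theta)[:, None], np.sin(theta)[:, None]
    ax = c[:, :, 0] * ct + c[:, :, 1] * st
    ay = -c[:, :, 0] * st + c[:, :, 1] * ct
    flip = (ax[:, -1] - ax[:, 0]) < 0.0  # net displacement must point +x
    ax[flip] *= -1.0
    ay[flip] *= -1.0
    out = np.stack([ax, ay], axis=2)
    return out[0] if single else out


def window_path_lengths(windows: Sequence[TrajectoryWindow]) -> np.ndarray:
    """Within-window path length (mm) for each window."""
    return np.array([
        float(np.hypot(np.diff(w.xy[:, 0]), np.diff(w.xy[:, 1])).sum())
        for w in windows
    ])


def window_displacements(windows: Sequence[TrajectoryWindow]) -> np.ndarray:
    """Net within-window displacement |end - start| (mm) for each window.

    Unlike raw path length, net displacement is robust to residual twitch
    jitter, which accumulates path without translating the fly; it is the
    quantity that separates walking from both low-motion states.
    """
    return np.array([
        float(np.hypot(*(w.xy[-1] - w.xy[0]))) for w in windows
    ])


# ---------------------------------------------------------------------------
# feature model
# ---------------------------------------------------------------------------

@dataclass
class FeatureModel:
    """Dataset-level principal-component basis over aligned windows.

    ``components`` is (K, 2W) orthonormal; features are the aligned, flattened
    window minus ``mean`` projected onto the components and divided by
    ``scale`` (per-component SD), so training features have unit variance.
    """

    window_w: int
    n_components: int
    mean: np.ndarray
    components: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("components must be orthonormal")


def _flatten_aligned(xy_stack: np.ndarray) -> np.ndarray:
    aligned = align_windows(xy_stack)
    return aligned.reshape(aligned.shape[0], -1)


def fit_feature_model(
    windows: Sequence[TrajectoryWindow],
    n_components: int = 5,
    min_windows_per_component: int = 50,
) -> FeatureModel:
    """Fit the alignment + PCA feature model on training windows."""
    if not windows:
        raise ValueError("no training windows")
    W = windows[0].xy.shape[0]
    if any(w.xy.shape[0] != W for w in windows):
        raise ValueError("all training windows must share one length")
    if len(windows) < n_components * min_windows_per_component:
        raise ValueError(
            f"need at least {n_components * min_windows_per_component} windows "
            f"to fit {n_components} components (got {len(windows)})"
        )
    X = _flatten_aligned(np.stack([w.xy for w in windows]))
    if float(X.var(axis=0).sum()) < 1e-12:
        raise ValueError(
            "degenerate training set: aligned windows are identical "
            "(e.g. all perfectly stationary)"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    scale = np.sqrt(pca.explained_variance_)
    if np.any(scale < 1e-12):
        raise ValueError(
            "degenerate training set: a retained component has zero variance"
        )
    return FeatureModel(
        window_w=W,
        n_components=n_components,
        mean=pca.mean_.copy(),
        components=pca.components_.copy(),
        scale=scale,
    )


def window_features(window, model: FeatureModel) -> np.ndarray:
    """Project one window (or a (N, W, 2) stack) onto the stored basis."""
    xy = window.xy if isinstance(window, TrajectoryWindow) else np.asarray(window, float)
    single = xy.ndim == 2
    stack = xy[None] if single else xy
    if stack.shape[1] != model.window_w:
        raise ValueError(
            f"window length {stack.shape[1]} != model window length {model.window_w}"
        )
    X = _flatten_aligned(stack)
    feats = (X - model.mean) @ model.components.T / model.scale
    return feats[0] if single else feats


# ---------------------------------------------------------------------------
# HMM
# ---------------------------------------------------------------------------

class _TraceMonitor(ConvergenceMonitor):
    """Convergence monitor that keeps the full log-likelihood trace."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: List[float] = []

    def report(self, log_prob: float) -> None:
        self.full_history.append(float(log_prob))
        super().report(log_prob)


@dataclass
class HmmModel:
    """Trained 3-state Gaussian HMM over window features.

    ``state_names[i]`` gives the behavioral label of hidden state ``i`` once
    :func:`assign_state_labels` has run; unlabeled models carry ``None``.
    Emission covariances are diagonal with a ridge floor.
    """

    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray
    covars: np.ndarray  # diagonal entries, (n_states, K)
    state_names: Optional[Tuple[str, ...]] = None
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, float)
        self.transmat = np.asarray(self.transmat, float)
        self.means = np.asarray(self.means, float)
        self.covars = np.asarray(self.covars, float)
        if abs(self.startprob.sum() - 1.0) > 1e-9:
            raise ValueError("startprob must sum to 1")
        if np.any(np.abs(self.transmat.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each transmat row must sum to 1")
        if np.any(self.covars <= 0):
            raise ValueError("emission variances must be positive")

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    @property
    def labeled(self) -> bool:
        return self.state_names is not None

    def to_hmmlearn(self) -> GaussianHMM:
        hm = GaussianHMM(n_components=self.n_states, covariance_type="diag")
        hm.n_features = self.means.shape[1]
        hm.startprob_ = self.startprob.copy()
        hm.transmat_ = self.transmat.copy()
        hm.means_ = self.means.copy()
        hm.covars_ = self.covars.copy()
        return hm

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Forward-backward posteriors, rows summing to 1."""
        return self.to_hmmlearn().predict_proba(np.asarray(X, float))


def kinematic_init(
    features: np.ndarray,
    displacements: np.ndarray,
    path_lengths: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Domain-informed initial emission parameters for Baum-Welch.

    Coarse kinematic sketch of the three motion regimes: a 1-d 2-means split
    on log net displacement separates walking from low-motion windows, and a
    second 2-means split on log path length separates twitchy immobilization
    from quiet pauses among the low-motion windows.  Returns per-state
    (means, diagonal covariances) in feature space; Baum-Welch refines from
    here.  This keeps unsupervised training anchored to the behavioral
    structure instead of whatever mixture maximizes likelihood fastest.
    """
    X = np.asarray(features, float)
    D = np.asarray(displacements, float)
    P = np.asarray(path_lengths, float)
    if not (len(X) == len(D) == len(P)):
        raise ValueError("features, displacements and path lengths must align")

    def split_1d(v: np.ndarray) -> np.ndarray:
        """2-means on a 1-d array; returns boolean mask of the upper cluster."""
        lo, hi = float(v.min()), float(v.max())
        if hi - lo < 1e-12:
            return np.zeros(len(v), bool)
        c = np.array([lo, hi])
        for _ in range(50):
            upper = np.abs(v - c[1]) < np.abs(v - c[0])
            if upper.all() or (~upper).all():
                break
            new = np.array([v[~upper].mean(), v[upper].mean()])
            if np.allclose(new, c):
                c = new
                break
            c = new
        return np.abs(v - c[1]) < np.abs(v - c[0])

    walk = split_1d(np.log10(D + 1e-3))
    low = ~walk
    immob = np.zeros(len(X), bool)
    if low.sum() >= 2:
        upper = split_1d(np.log10(P[low] + 1e-3))
        idx = np.flatnonzero(low)
        immob[idx[upper]] = True
    pause = low & ~immob
    groups = [walk, pause, immob]
    gvar = X.var(axis=0) + 1e-6
    means, covs = [], []
    for g in groups:
        if g.sum() >= 2:
            means.append(X[g].mean(axis=0))
            covs.append(X[g].var(axis=0) + 1e-6)
        else:  # regime absent in training data; fall back to the global cloud
            means.append(X.mean(axis=0))
            covs.append(gvar)
    return np.array(means), np.array(covs)


def train_classifier(
    features_by_fly: Sequence[np.ndarray],
    n_states: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
    n_iter: int = 200,
    tol: float = 1e-3,
    ridge: float = 1e-6,
    init_means: Optional[np.ndarray] = None,
    init_covars: Optional[np.ndarray] = None,
) -> HmmModel:
    """Baum-Welch training with seeded restarts; best log-likelihood retained.

    ``features_by_fly`` holds one (n_windows, K) feature sequence per fly, in
    window order.  The returned model is *unlabeled*; run
    :func:`assign_state_labels` before decoding.  Restart ``r`` uses random
    state ``seed + r``, all recorded in metadata together with the winning
    restart's per-iteration log-likelihood trace (non-decreasing, an EM
    guarantee).

    When ``init_means``/``init_covars`` are given (e.g. from
    :func:`kinematic_init`), every restart starts from a seeded perturbation
    of them and Baum-Welch refines; otherwise hmmlearn's k-means
    initialization is used per restart.
    """
    seqs = [np.atleast_2d(np.asarray(f, float)) for f in features_by_fly]
    if len(seqs) < 2:
        raise ValueError("training requires feature sequences from >= 2 flies")
    if any(len(s) < 10 for s in seqs):
        raise ValueError("each training sequence must contain >= 10 windows")
    X = np.vstack(seqs)
    lengths = [len(s) for s in seqs]
    best = None
    for r in range(n_restarts):
        informed = init_means is not None
        hm = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=n_iter,
            tol=tol,
            random_state=seed + r,
            min_covar=ridge,
            init_params="st" if informed else "stmc",
        )
        if informed:
            rng = np.random.default_rng(seed + r)
            sd = np.sqrt(init_covars if init_covars is not None
                         else np.tile(X.var(axis=0), (n_states, 1)))
            jitter = 0.0 if r == 0 else 0.25 * rng.normal(size=init_means.shape)
            hm.means_ = init_means + jitter * sd
            hm.covars_ = (init_covars if init_covars is not None
                          else np.tile(X.var(axis=0), (n_states, 1))).copy()
        hm.monitor_ = _TraceMonitor(hm.tol, hm.n_iter, hm.verbose)
        hmm_logger = logging.getLogger("hmmlearn.base")
        prev_level = hmm_logger.level
        hmm_logger.setLevel(logging.ERROR)  # ridge-regularized M-steps can
        try:                                # oscillate below tol at the end
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hm.fit(X, lengths)
        finally:
            hmm_logger.setLevel(prev_level)
        trace = hm.monitor_.full_history
        score = trace[-1]
        if best is None or score > best[0]:
            best = (score, hm, list(trace), bool(hm.monitor_.converged))
    score, hm, trace, converged = best
    if not converged:
        warnings.warn("Baum-Welch did not converge within n_iter; "
                      "returning the best model found", stacklevel=2)
    return HmmModel(
        startprob=hm.startprob_,
        transmat=hm.transmat_,
        means=hm.means_,
        covars=np.array([np.diag(c) for c in hm.covars_]),
        metadata={
            "seed": int(seed),
            "n_restarts": int(n_restarts),
            "n_iter": int(n_iter),
            "tol": float(tol),
            "ridge": float(ridge),
            "log_likelihood": float(score),
            "loglik_trace": [float(v) for v in trace],
            "converged": converged,
        },
    )


def assign_state_labels(
    model: HmmModel,
    features_by_fly: Sequence[np.ndarray],
    motion_by_fly: Sequence[np.ndarray],
) -> HmmModel:
    """Label hidden states by their kinematic signature.

    The state with the greatest *expected within-window motion*
    (posterior-weighted mean of the per-window net displacement, a
    jitter-robust stand-in for forward travel) becomes ``walking``; of the
    two low-motion states, the one with the higher self-transition
    probability (longer dwell) becomes ``immobilized`` and the other
    ``pausing``.  Ties break deterministically by state index.
    """
    if model.n_states != 3:
        raise ValueError("labeling rule is defined for 3-state models")
    gam = np.vstack([model.predict_proba(f) for f in features_by_fly])
    L = np.concatenate([np.asarray(p, float) for p in motion_by_fly])
    if len(L) != len(gam):
        raise ValueError("motion measures must align with feature windows")
    mass = gam.sum(axis=0)
    if np.any(mass < 1e-6 * len(gam)):
        warnings.warn(
            "a hidden state captures almost no training windows; "
            "fewer motion regimes than states — labels may collapse",
            stacklevel=2,
        )
    expected_L = (gam * L[:, None]).sum(axis=0) / np.maximum(mass, 1e-300)
    order = np.argsort(-expected_L, kind="stable")
    walking = int(order[0])
    low = sorted(int(s) for s in order[1:])
    self_p = np.array([model.transmat[s, s] for s in low])
    if abs(self_p[0] - self_p[1]) < 1e-12:
        logger.info("equal self-transitions among low-motion states; "
                    "tie broken by state index")
        immobilized, pausing = low[0], low[1]
    else:
        immobilized = low[int(np.argmax(self_p))]
        pausing = low[0] if immobilized == low[1] else low[1]
    names = [""] * 3
    names[walking] = "walking"
    names[pausing] = "pausing"
    names[immobilized] = "immobilized"
    return replace(model, state_names=tuple(names))


def viterbi_path(model: HmmModel, features: np.ndarray) -> np.ndarray:
    """Most probable joint state path (max-product) for a feature sequence."""
    return model.to_hmmlearn().predict(np.asarray(features, float))


# ---------------------------------------------------------------------------
# decoding and immobilization summaries
# ---------------------------------------------------------------------------

@dataclass
class StateSequence:
    """Per-frame behavioral labels with posterior confidence."""

    fly_id: str
    fps: float
    time_s: np.ndarray
    states: np.ndarray       # int codes into STATES
    confidence: np.ndarray   # posterior of the reported label, in [0, 1]
    posteriors: Optional[np.ndarray] = None  # (n_frames, 3) in STATES order

    def __post_init__(self) -> None:
        if not (len(self.time_s) == len(self.states) == len(self.confidence)):
            raise ValueError("state sequence arrays must share a common length")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> np.ndarray:
        return np.array(STATES, dtype=object)[self.states]


def _frame_scale_transmat(transmat: np.ndarray, window_w: int) -> np.ndarray:
    """Rescale a per-window transition matrix to a per-frame step.

    Training estimates transitions at the non-overlapping-window time scale;
    stride-1 decoding steps one frame at a time, so the matrix is taken to
    the 1/W power (via eigendecomposition, clipped to the simplex).  Falls
    back to the original matrix if the root is not well behaved.
    """
    try:
        w, v = np.linalg.eig(transmat)
        root = (v @ np.diag(np.power(w.astype(complex), 1.0 / window_w))
                @ np.linalg.inv(v))
        root = np.real(root)
    except np.linalg.LinAlgError:
        return transmat
    if np.any(~np.isfinite(root)):
        return transmat
    root = np.clip(root, 1e-12, None)
    return root / root.sum(axis=1, keepdims=True)


def decode_states(
    model: HmmModel,
    traj: Trajectory,
    feature_model: FeatureModel,
    max_interp_fraction: float = 0.25,
) -> StateSequence:
    """Frame-wise decoding via forward-backward over stride-1 windows.

    Each frame takes the max-posterior state of its centred window; edge
    frames (and frames whose centred window exceeds the interpolated-frame
    limit) use the nearest valid window.  Per-frame posteriors over the three
    states sum to 1.  The transition matrix is rescaled to the frame step
    (matrix 1/W power) so dwell expectations keep their trained time scale.
    """
    if not model.labeled:
        raise ValueError("model must be labeled before decoding")
    W = feature_model.window_w
    n = len(traj)
    if n < W:
        raise ValueError("trajectory shorter than the classifier window")
    xy = traj.xy
    starts = np.arange(n - W + 1)
    stack = np.stack([xy[s:s + W] for s in starts])  # (n-W+1, W, 2)
    feats = window_features(stack, feature_model)
    frame_model = replace(model,
                          transmat=_frame_scale_transmat(model.transmat, W))
    gamma = frame_model.predict_proba(feats)  # window posteriors, model order

    # reorder columns into canonical STATES order
    col = [model.state_names.index(name) for name in STATES]
    gamma = gamma[:, col]

    # window validity under the interpolation rule
    gap = traj.gap_mask.astype(float)
    csum = np.concatenate([[0.0], np.cumsum(gap)])
    frac = (csum[W:] - csum[:-W]) / W
    valid = frac <= max_interp_fraction
    if not valid.any():
        raise ValueError("no decoding window passes the interpolation limit")
    valid_idx = np.flatnonzero(valid)

    centred = np.clip(np.arange(n) - (W - 1) // 2, 0, n - W)
    # snap invalid centred windows to the nearest valid window start
    pos = np.searchsorted(valid_idx, centred)
    pos = np.clip(pos, 0, len(valid_idx) - 1)
    left = valid_idx[np.maximum(pos - 1, 0)]
    right = valid_idx[pos]
    use_left = np.abs(centred - left) <= np.abs(right - centred)
    snapped = np.where(valid[centred], centred, np.where(use_left, left, right))

    post = gamma[snapped]
    states = post.argmax(axis=1).astype(np.int8)
    conf = post[np.arange(n), states]
    return StateSequence(traj.fly_id, traj.fps, traj.time_s.copy(),
                         states, conf, posteriors=post)


@dataclass(frozen=True)
class ImmobilizationSummary:
    """Per-interval immobilization totals for one fly."""

    fly_id: str
    interval: str
    total_immobilized_s: float
    longest_bout_s: float
    incidence: bool  # any contiguous immobilized bout >= min_bout_s
    onset_time_s: Optional[float]  # absolute time of first qualifying bout

    def __post_init__(self) -> None:
        if self.longest_bout_s > self.total_immobilized_s + 1e-9:
            raise ValueError("longest bout cannot exceed the total")
        if self.incidence and self.onset_time_s is None:
            raise ValueError("incidence requires an onset time")


def immobilization_summary(
    seq: StateSequence,
    interval: AnalysisInterval,
    min_bout_s: float = 2.0,
) -> ImmobilizationSummary:
    """Summarize immobilized bouts within an analysis window.

    Incidence requires at least one contiguous immobilized bout of
    ``min_bout_s`` (default 2 s, the seizure-incidence criterion).
    """
    m = (seq.time_s >= interval.start_s - 1e-9) & (seq.time_s < interval.end_s - 1e-9)
    if not m.any():
        raise ValueError(f"interval {interval.name!r} outside the state sequence")
    imm = (seq.states == STATES.index("immobilized")) & m
    total = float(imm.sum() / seq.fps)
    longest = 0.0
    incidence = False
    onset: Optional[float] = None
    run_start = None
    padded = np.concatenate([imm, [False]])
    for i, v in enumerate(padded):
        if v and run_start is None:
            run_start = i
        elif not v and run_start is not None:
            dur = (i - run_start) / seq.fps
            longest = max(longest, dur)
            if dur >= min_bout_s and onset is None:
                onset = float(seq.time_s[run_start])
                incidence = True
            run_start = None
    return ImmobilizationSummary(seq.fly_id, interval.name, total, longest,
                                 incidence, onset)


def cumulative_onset_curve(
    summaries: Sequence[ImmobilizationSummary],
    interval: AnalysisInterval,
    dt_s: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Cohort cumulative incidence: fraction of flies with onset <= t.

    Returns ``(times, fraction)`` over the analysis window; flies without a
    qualifying bout never contribute.
    """
    if not summaries:
        raise ValueError("no summaries")
    t = np.arange(interval.start_s, interval.end_s + dt_s / 2, dt_s)
    onsets = np.array([s.onset_time_s for s in summaries if s.onset_time_s is not None])
    frac = np.array([(onsets <= ti).sum() / len(summaries) for ti in t])
    return t, frac


# ---------------------------------------------------------------------------
# convenience training entry point and serialization
# ---------------------------------------------------------------------------

def train_behavior_classifier(
    trajectories: Sequence[Trajectory],
    window_s: float = 2.0,
    n_components: int = 5,
    seed: int = 0,
    n_restarts: int = 10,
    min_windows_per_component: int = 50,
    **train_kwargs,
) -> Tuple[HmmModel, FeatureModel]:
    """Full training pass: windows -> feature model -> HMM -> labeled model.

    Baum-Welch restarts are initialized from the kinematic sketch of
    :func:`kinematic_init` so the three states anchor to the walking /
    pausing / immobilized motion regimes.
    """
    windows_by_fly = [segment_windows(t, window_s=window_s) for t in trajectories]
    all_windows = [w for ws in windows_by_fly for w in ws]
    fm = fit_feature_model(all_windows, n_components=n_components,
                           min_windows_per_component=min_windows_per_component)
    feats, paths, disps = [], [], []
    for ws in windows_by_fly:
        stack = np.stack([w.xy for w in ws])
        feats.append(window_features(stack, fm))
        paths.append(window_path_lengths(ws))
        disps.append(window_displacements(ws))
    means0, covars0 = kinematic_init(np.vstack(feats), np.concatenate(disps),
                                     np.concatenate(paths))
    model = train_classifier(feats, n_states=3, seed=seed,
                             n_restarts=n_restarts, init_means=means0,
                             init_covars=covars0, **train_kwargs)
    model = assign_state_labels(model, feats, disps)
    return model, fm


def save_model(path, model: HmmModel, feature_model: FeatureModel) -> None:
    """Write model + feature basis to a versioned JSON container."""
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "hmm": {
            "startprob": model.startprob.tolist(),
            "transmat": model.transmat.tolist(),
            "means": model.means.tolist(),
            "covars": model.covars.tolist(),
            "state_names": list(model.state_names) if model.state_names else None,
            "metadata": model.metadata,
        },
        "feature_model": {
            "window_w": feature_model.window_w,
            "n_components": feature_model.n_components,
            "mean": feature_model.mean.tolist(),
            "components": feature_model.components.tolist(),
            "scale": feature_model.scale.tolist(),
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path) -> Tuple[HmmModel, FeatureModel]:
    """Load a model container; refuses mismatched format versions."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != MODEL_FORMAT or doc.get("version") != MODEL_VERSION:
        raise ValueError(
            f"unsupported model container {doc.get('format')!r} "
            f"version {doc.get('version')!r} (expected {MODEL_FORMAT} v{MODEL_VERSION})"
        )
    h = doc["hmm"]
    model = HmmModel(
        startprob=np.array(h["startprob"]),
        transmat=np.array(h["transmat"]),
        means=np.array(h["means"]),
        covars=np.array(h["covars"]),
        state_names=tuple(h["state_names"]) if h["state_names"] else None,
        metadata=h.get("metadata", {}),
    )
    f = doc["feature_model"]
    fm = FeatureModel(
        window_w=int(f["window_w"]),
        n_components=int(f["n_components"]),
        mean=np.array(f["mean"]),
        components=np.array(f["components"]),
        scale=np.array(f["scale"]),
    )
    return model, fm
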