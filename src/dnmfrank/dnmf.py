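"""Discriminant non-negative matrix factorization under a KL objective.

The model approximates a nonnegative expression matrix ``V`` (genes x
samples) by the product of two nonnegative factors, ``V ~ W H``, where
``W`` (genes x K) holds per-gene metagene weights and ``H`` (K x samples)
holds per-sample metagene expression.  The loss is the generalized
Kullback-Leibler divergence

    D(V || WH) = sum_il [ V_il ln(V_il/(WH)_il) - V_il + (WH)_il ],

penalized by Fisher's discriminant criterion on the columns of ``H``:

    F(W, H) = D(V || WH) + gamma * tr(Sw) - delta * tr(Sb),

with ``Sw`` the within-class and ``Sb`` the between-class scatter of the
sample coefficient vectors.  Minimization alternates multiplicative
updates: the ``W`` step is the standard KL-NMF rule followed by column
normalization (each column of ``W`` sums to one); the ``H`` step solves,
for every entry, the nonnegative root of a per-entry quadratic whose
coefficients carry the penalty terms.

With ``gamma = delta = 0`` the procedure reduces exactly to Lee-Seung
KL-NMF (in the column-normalized gauge), which is the main correctness
oracle used by the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import ClassLabels, ExpressionMatrix

__all__ = [
    "ScatterSummary",
    "FitTrace",
    "DegenerateOrientationError",
    "kl_divergence",
    "class_statistics",
    "objective",
    "class_seed_H",
    "initialize_factors",
    "update_H",
    "update_W",
    "fit_dnmf",
    "DiscriminantNMF",
]

# floor added to denominators before division
EPS_DEFAULT = 1e-16


class DegenerateOrientationError(RuntimeError):
    """Raised when no refit yields one up- and one down-regulated metagene."""


@dataclass
class ScatterSummary:
    """Class means of H's sample coefficients and their scatter matrices."""

    class_means: np.ndarray  # (R, K)
    grand_mean: np.ndarray  # (K,)
    Sw: np.ndarray  # (K, K) within-class scatter
    Sb: np.ndarray  # (K, K) between-class scatter


@dataclass
class FitTrace:
    """Per-iteration diagnostics of one factorization run."""

    objective_per_iteration: list[float] = field(default_factory=list)
    kl_per_iteration: list[float] = field(default_factory=list)
    iterations_run: int = 0
    reruns_used: int = 0
    converged: bool = False


def _as_array(V) -> np.ndarray:
    if isinstance(V, ExpressionMatrix):
        V = V.values
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be two-dimensional")
    if np.any(V < 0) or not np.all(np.isfinite(V)):
        raise ValueError("V must be nonnegative and finite")
    return V


def _class_index(labels, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (class index per sample, class sizes)."""
    if isinstance(labels, ClassLabels):
        raise TypeError(
            "pass an explicit sample order: use labels.indices(sample_ids)"
        )
    idx = np.asarray(labels)
    if idx.shape != (n_samples,):
        raise ValueError("one class label per H column is required")
    if idx.dtype.kind not in "iu":
        # arbitrary labels: order of first appearance
        _, first = np.unique(idx, return_index=True)
        order = idx[np.sort(first)]
        lut = {c: r for r, c in enumerate(order)}
        idx = np.array([lut[c] for c in idx], dtype=np.intp)
    idx = idx.astype(np.intp)
    R = idx.max() + 1
    sizes = np.bincount(idx, minlength=R)
    if np.any(sizes == 0):
        raise ValueError("every class must contain at least one sample")
    return idx, sizes


def kl_divergence(V, W, H) -> float:
    """Generalized KL divergence between ``V`` and ``W @ H``.

    Uses the ``0 * ln 0 = 0`` convention; returns ``inf`` when some
    ``V_il > 0`` meets ``(WH)_il = 0``.
    """
    V = _as_array(V)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(W < 0) or np.any(H < 0):
        raise ValueError("factors must be nonnegative")
    if W.shape[0] != V.shape[0] or H.shape[1] != V.shape[1] or W.shape[1] != H.shape[0]:
        raise ValueError("factor shapes do not conform to V")
    WH = W @ H
    pos = V > 0
    if np.any(WH[pos] == 0):
        return float("inf")
    total = float(WH.sum() - V.sum())
    total += float(np.sum(V[pos] * np.log(V[pos] / WH[pos])))
    return total


def class_statistics(H, labels) -> ScatterSummary:
    """Class means, grand mean, and Fisher scatter matrices of ``H``.

    The grand mean is the mean over all ``L`` columns of ``H`` (not the
    mean of class means), so classes of unequal size are weighted by their
    sample counts.
    """
    H = np.asarray(H, dtype=float)
    idx, sizes = _class_index(labels, H.shape[1])
    K = H.shape[0]
    R = sizes.shape[0]
    class_means = np.empty((R, K))
    for r in range(R):
        class_means[r] = H[:, idx == r].mean(axis=1)
    grand_mean = H.mean(axis=1)
    Sw = np.zeros((K, K))
    for r in range(R):
        D = H[:, idx == r] - class_means[r][:, None]
        Sw += D @ D.T
    diff = class_means - grand_mean  # (R, K)
    Sb = (diff * sizes[:, None]).T @ diff
    return ScatterSummary(class_means, grand_mean, Sw, Sb)


def objective(V, W, H, labels, gamma: float, delta: float) -> float:
    """Penalized loss ``KL(V||WH) + gamma*tr(Sw) - delta*tr(Sb)``."""
    stats = class_statistics(H, labels)
    return (
        kl_divergence(V, W, H)
        + gamma * float(np.trace(stats.Sw))
        - delta * float(np.trace(stats.Sb))
    )


def class_seed_H(H: np.ndarray, labels) -> np.ndarray:
    """Add the total sum of all ``H`` entries to row ``k`` over class ``k``.

    The anchoring step of the class-seeded initialization: since the added
    scalar ``S`` exceeds every individual entry, each metagene row starts
    strictly dominant on its own class.
    """
    H = np.asarray(H, dtype=float)
    idx, sizes = _class_index(labels, H.shape[1])
    if H.shape[0] != sizes.shape[0]:
        raise ValueError("class seeding needs one metagene row per class")
    out = H.copy()
    S = H.sum()
    for k in range(H.shape[0]):
        out[k, idx == k] += S
    return out


def initialize_factors(
    n_genes: int,
    labels,
    n_components: int,
    rng: np.random.Generator,
    class_seeded: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Random initialization with class seeding of ``H``.

    ``W`` and ``H`` are drawn uniform(0, 1); then, when one metagene is
    allotted per class (K = R), the total sum ``S`` of all freshly drawn
    ``H`` entries is added to row ``k`` of ``H`` over the samples of class
    ``r = k``.  Because ``S`` exceeds every individual entry, row ``k`` is
    then strictly dominant on its own class, which anchors one metagene per
    class from the start.  ``W`` columns are normalized to sum to one.
    """
    idx, sizes = _class_index(labels, np.asarray(labels).shape[0])
    L = idx.shape[0]
    K = n_components
    W = rng.uniform(size=(n_genes, K))
    H = rng.uniform(size=(K, L))
    if class_seeded:
        if K != sizes.shape[0]:
            raise ValueError(
                f"class-seeded initialization needs one metagene per class "
                f"(K={K}, classes={sizes.shape[0]}); use class_seeded=False "
                "for a purely random start"
            )
        H = class_seed_H(H, idx)
    W /= W.sum(axis=0, keepdims=True)
    return W, H


def update_W(V, W, H, eps: float = EPS_DEFAULT) -> np.ndarray:
    """One multiplicative update of ``W`` followed by column normalization.

    ``w_ik <- w_ik * sum_l (V_il/(WH)_il) h_kl``, then each column is
    divided by its sum so that columns of the returned matrix sum to one.
    """
    V = _as_array(V)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    WH = W @ H
    Wn = W * ((V / (WH + eps)) @ H.T)
    colsums = Wn.sum(axis=0)
    if np.any(colsums <= 0) or not np.all(np.isfinite(colsums)):
        raise FloatingPointError(
            "a metagene column of W collapsed to zero; re-initialize with a "
            "different seed"
        )
    return Wn / colsums


def _h_quadratic_coefficients(V, W, H, labels, gamma, delta, eps):
    """Per-entry quadratic coefficients (a, b, c) of the H update.

    For entry ``h_kl`` with sample ``l`` in class ``r`` (``Nr`` samples,
    ``L`` total), the stationarity condition of the penalized auxiliary
    function is ``a h^2 + b h + c = 0`` with

        a = 2*gamma + 2*delta/L - (2*gamma + 2*delta)/Nr
        b = 1 + (2*delta/L) * sum_{j != l} h_kj
              - ((2*gamma + 2*delta)/Nr) * sum_{lambda != l, class r} h_k,lambda
        c = - h_kl * sum_i V_il w_ik / (WH)_il   (<= 0)

    ``a`` is a scalar per class; ``b`` and ``c`` are (K, L) arrays.  The
    leading 1 in ``b`` is the column sum of ``W``, which is one in the
    normalized gauge.
    """
    idx, sizes = _class_index(labels, H.shape[1])
    L = H.shape[1]
    Nr = sizes[idx].astype(float)  # per sample
    a = 2.0 * gamma + 2.0 * delta / L - (2.0 * gamma + 2.0 * delta) / Nr  # (L,)
    row_sums = H.sum(axis=1, keepdims=True)  # (K, 1)
    class_sums = np.stack(
        [H[:, idx == r].sum(axis=1) for r in range(sizes.shape[0])], axis=1
    )  # (K, R)
    b = (
        1.0
        + (2.0 * delta / L) * (row_sums - H)
        - ((2.0 * gamma + 2.0 * delta) / Nr) * (class_sums[:, idx] - H)
    )
    WH = W @ H
    c = -H * (W.T @ (V / (WH + eps)))
    return np.broadcast_to(a, H.shape), b, c


def update_H(
    V,
    W,
    H,
    labels,
    gamma: float,
    delta: float,
    eps: float = EPS_DEFAULT,
) -> np.ndarray:
    """One penalized multiplicative update of ``H``.

    Each entry is replaced by the nonnegative root of its quadratic,
    ``(-b + sqrt(b^2 - 4ac)) / (2a)``, computed in the numerically stable
    form ``-2c / (b + sqrt(b^2 - 4ac))``; with ``a = 0`` (no penalty) the
    update degenerates to ``-c/b``, the Lee-Seung KL rule for
    column-normalized ``W``.
    """
    V = _as_array(V)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    a, b, c = _h_quadratic_coefficients(V, W, H, labels, gamma, delta, eps)
    disc = b * b - 4.0 * a * c
    if np.any(disc < -1e-12 * np.maximum(b * b, 1.0)):
        raise FloatingPointError("negative discriminant in the H update")
    sqrt_disc = np.sqrt(np.maximum(disc, 0.0))
    Hn = np.empty_like(H)
    linear = a == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        Hn[linear] = -c[linear] / b[linear]
        denom = b + sqrt_disc
        quad = ~linear
        Hn[quad] = np.where(denom[quad] > 0.0, -2.0 * c[quad] / denom[quad],
                            (-b[quad] + sqrt_disc[quad]) / (2.0 * a[quad]))
    if np.any(Hn < 0) or not np.all(np.isfinite(Hn)):
        raise FloatingPointError("H update produced negative or non-finite entries")
    return Hn


def fit_dnmf(
    V,
    labels,
    n_components: int = 2,
    gamma: float = 0.1,
    delta: float = 1e-4,
    max_iter: int = 1000,
    tol: float = 1e-6,
    eps: float = EPS_DEFAULT,
    random_state: int | np.random.Generator | None = 0,
    max_reruns: int = 10,
    ensure_orientation: bool = True,
    class_seeded: bool = True,
) -> tuple[np.ndarray, np.ndarray, FitTrace]:
    """Fit the penalized factorization ``V ~ W H``; returns ``(W, H, trace)``.

    ``V`` is genes x samples; ``labels`` gives one class per column (class
    index array, label array, or ``ClassLabels.indices`` output).  Each
    iteration runs the ``W`` update (with normalization) then the ``H``
    update and records the penalized objective; iteration stops when the
    relative objective change drops below ``tol`` or at ``max_iter``.

    Converged fits may still fail to split the two metagenes into one
    up-regulated and one down-regulated pattern.  When
    ``ensure_orientation`` is set (requires K = 2 and two classes), such
    degenerate fits are retried from a reseeded random start up to
    ``max_reruns`` times before :class:`DegenerateOrientationError` is
    raised.
    """
    V = _as_array(V)
    idx, sizes = _class_index(labels, V.shape[1])
    if sizes.shape[0] < 2:
        raise ValueError(
            "at least two sample classes are required; the discriminant "
            "penalty and gene ranking are undefined for a single class"
        )
    if ensure_orientation and (n_components != 2 or sizes.shape[0] != 2):
        raise ValueError("orientation checking requires K = 2 and two classes")
    if isinstance(random_state, np.random.Generator):
        base_seed = int(random_state.integers(2**31 - 1))
    else:
        base_seed = 0 if random_state is None else int(random_state)

    from .ranking import orient_metagenes  # deferred: ranking imports this module

    last_err: Exception | None = None
    for rerun in range(max_reruns + 1):
        rng = np.random.default_rng((base_seed + rerun) % 2**31)
        W, H = initialize_factors(V.shape[0], idx, n_components, rng, class_seeded)
        trace = FitTrace(reruns_used=rerun)
        obj = objective(V, W, H, idx, gamma, delta)
        for _ in range(max_iter):
            W = update_W(V, W, H, eps)
            H = update_H(V, W, H, idx, gamma, delta, eps)
            new_obj = objective(V, W, H, idx, gamma, delta)
            if not np.isfinite(new_obj):
                raise FloatingPointError(
                    f"non-finite objective at iteration {trace.iterations_run}"
                )
            trace.objective_per_iteration.append(new_obj)
            trace.kl_per_iteration.append(kl_divergence(V, W, H))
            trace.iterations_run += 1
            if abs(new_obj - obj) <= tol * max(abs(obj), 1e-300):
                trace.converged = True
                obj = new_obj
                break
            obj = new_obj
        if not ensure_orientation:
            return W, H, trace
        orientation = orient_metagenes(H, idx)
        if not orientation.degenerate:
            return W, H, trace
        last_err = DegenerateOrientationError(
            f"metagenes did not separate into up/down after "
            f"{rerun + 1} run(s)"
        )
    raise DegenerateOrientationError(
        f"no orientation-consistent fit in {max_reruns + 1} runs (seed "
        f"{base_seed}); the classes may not be separable"
    ) from last_err


class DiscriminantNMF(BaseEstimator):
    """Supervised NMF with a Fisher-criterion penalty (KL loss).

    Decomposes expression data into ``K`` metagenes whose per-sample
    coefficients are pushed to cluster within classes and separate between
    classes.  Follows the scikit-learn convention: ``X`` is samples x
    features (genes), ``y`` is one class label per sample; internally the
    model factorizes ``V = X.T``.

    Parameters
    ----------
    n_components : int, default 2
        Number of metagenes K.  Gene ranking requires 2.
    gamma : float, default 0.1
        Weight of the within-class scatter ``tr(Sw)`` penalty.
    delta : float, default 1e-4
        Weight of the between-class scatter ``tr(Sb)`` reward.
    max_iter, tol : stopping rule — relative objective change below
        ``tol`` or ``max_iter`` iterations.
    ensure_orientation : bool, default True
        Retry from fresh random starts (up to ``max_reruns``) until the two
        metagenes split into one up- and one down-regulated pattern.
    class_seeded : bool, default True
        Use the class-anchored initialization of ``H``.

    Attributes
    ----------
    W_ : ndarray (n_features, K)
        Gene weights per metagene; columns sum to one.
    H_ : ndarray (K, n_samples)
        Metagene expression per training sample.
    components_ : ndarray (K, n_features)
        ``W_.T``, for scikit-learn interoperability.
    trace_ : FitTrace
    classes_ : ndarray of the distinct labels, control first.
    """

    def __init__(
        self,
        n_components: int = 2,
        gamma: float = 0.1,
        delta: float = 1e-4,
        max_iter: int = 1000,
        tol: float = 1e-6,
        eps: float = EPS_DEFAULT,
        random_state: int | None = 0,
        max_reruns: int = 10,
        ensure_orientation: bool = True,
        class_seeded: bool = True,
    ) -> None:
        self.n_components = n_components
        self.gamma = gamma
        self.delta = delta
        self.max_iter = max_iter
        self.tol = tol
        self.eps = eps
        self.random_state = random_state
        self.max_reruns = max_reruns
        self.ensure_orientation = ensure_orientation
        self.class_seeded = class_seeded

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be samples x genes")
        if y.shape[0] != X.shape[0]:
            raise ValueError("one label per sample is required")
        _, first = np.unique(y, return_index=True)
        self.classes_ = y[np.sort(first)]
        lut = {c: r for r, c in enumerate(self.classes_)}
        idx = np.array([lut[c] for c in y], dtype=np.intp)
        self.W_, self.H_, self.trace_ = fit_dnmf(
            X.T,
            idx,
            n_components=self.n_components,
            gamma=self.gamma,
            delta=self.delta,
            max_iter=self.max_iter,
            tol=self.tol,
            eps=self.eps,
            random_state=self.random_state,
            max_reruns=self.max_reruns,
            ensure_orientation=self.ensure_orientation,
            class_seeded=self.class_seeded,
        )
        self.components_ = self.W_.T
        self.n_iter_ = self.trace_.iterations_run
        self.reconstruction_err_ = self.trace_.kl_per_iteration[-1]
        return self

    def fit_transform(self, X, y):
        """Fit and return the per-sample metagene coefficients ``H_.T``."""
        self.fit(X, y)
        return self.H_.T

    def score(self, X=None, y=None) -> float:
        """Negative final penalized objective of the fitted model."""
        check_is_fitted(self, "trace_")
        return -self.trace_.objective_per_iteration[-1]
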