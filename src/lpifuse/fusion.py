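"""Feature fusion, scaling, and SVM-RFE with correlation bias reduction.

The five feature blocks are concatenated column-wise in a fixed order
(topology, K-PSSM, CTD, lncRNA sequence, expression) into one matrix whose
column provenance is recorded as block spans.

Feature ranking uses recursive feature elimination driven by a kernel SVM.
At each iteration an SVM is trained on the surviving features and every
surviving feature f is scored by the change in the dual objective when f
is dropped from the kernel:

    DJ(f) = 1/2 * (a' K a  -  a' K_(-f) a)

where a are the signed dual coefficients on the support vectors, K the
kernel matrix over support vectors and K_(-f) the same kernel recomputed
without feature f. For the RBF kernel K_(-f) = K * exp(gamma * d_f^2)
elementwise (d_f the pairwise differences in feature f); for the linear
kernel K_(-f) = K - x_f x_f'. The lowest-scoring features are eliminated
and appended to the tail of the ranking.

Correlation bias reduction (CBR): groups of highly correlated surviving
features (|Pearson r| >= r_th, grouped by connected components) mutually
mask each other's importance, so at most one member of any group is
eliminated per iteration; the rest re-enter the next iteration with their
criteria recomputed after the removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .io import ValidationError
from .network import FeatureBlock

#: Canonical fusion order of the five feature blocks.
BLOCK_ORDER = ("LDNet", "KPSSM", "CTD", "SEQ", "EXPR")


@dataclass
class FusedDataset:
    """Fused feature matrix with labels and column provenance."""

    matrix: np.ndarray
    labels: np.ndarray
    block_spans: dict[str, tuple[int, int]]
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValidationError("labels length must match matrix rows")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be binary 0/1")
        spans = sorted(self.block_spans.values())
        covered = 0
        for start, stop in spans:
            if start != covered:
                raise ValidationError("block spans must be disjoint and covering")
            covered = stop
        if covered != self.matrix.shape[1]:
            raise ValidationError("block spans must cover all columns")
        if not self.feature_names:
            self.feature_names = [f"f{k}" for k in range(self.matrix.shape[1])]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def fuse(blocks: list[FeatureBlock], labels) -> FusedDataset:
    """Concatenate feature blocks column-wise; rows must share one pair list."""
    if not blocks:
        raise ValidationError("need at least one feature block")
    ref = blocks[0].pair_list
    for b in blocks[1:]:
        if b.pair_list != ref:
            raise ValidationError(
                f"block {b.name!r} pair list differs from {blocks[0].name!r}"
            )
    order = {name: k for k, name in enumerate(BLOCK_ORDER)}
    blocks = sorted(blocks, key=lambda b: order.get(b.name, len(order)))
    spans: dict[str, tuple[int, int]] = {}
    names: list[str] = []
    start = 0
    for b in blocks:
        spans[b.name] = (start, start + b.dim)
        names.extend(b.feature_names())
        start += b.dim
    return FusedDataset(np.hstack([b.matrix for b in blocks]), labels, spans, names)


# ---------------------------------------------------------------------------
# Min-max scaling

class MinMax:
    """Per-column [0, 1] scaling fitted on training rows only.

    Constant training columns map to 0; test rows may fall outside [0, 1].
    """

    def __init__(self) -> None:
        self._scaler: MinMaxScaler | None = None

    def fit(self, train_rows: np.ndarray) -> "MinMax":
        self._scaler = MinMaxScaler(clip=False).fit(np.asarray(train_rows, dtype=float))
        return self

    def transform(self, rows: np.ndarray) -> np.ndarray:
        if self._scaler is None:
            raise ValidationError("MinMax.transform called before fit")
        return self._scaler.transform(np.asarray(rows, dtype=float))


def fit_minmax(train_rows: np.ndarray) -> MinMax:
    return MinMax().fit(train_rows)


def apply_minmax(scaler: MinMax, rows: np.ndarray) -> np.ndarray:
    return scaler.transform(rows)


# ---------------------------------------------------------------------------
# SVM-RFE + CBR

@dataclass
class RfeParams:
    """SVM-RFE + CBR parameters.

    Defaults follow the selector's published configuration: RBF kernel with
    C = 16 and gamma = 0.0078, CBR enabled with correlation threshold 0.9.
    ``step`` is the number of features eliminated per iteration; a value in
    (0, 1) removes that fraction of the survivors (at least one).
    """

    kernel_type: str = "rbf"
    rfe_C: float = 16.0
    rfe_gamma: float = 0.0078
    use_cbr: bool = True
    r_th: float = 0.9
    step: float = 1

    def __post_init__(self) -> None:
        if self.kernel_type not in ("linear", "rbf"):
            raise ValidationError("kernel_type must be 'linear' or 'rbf'")
        if self.rfe_C <= 0 or self.rfe_gamma <= 0:
            raise ValidationError("rfe_C and rfe_gamma must be positive")
        if not (0 < self.r_th <= 1):
            raise ValidationError("r_th must be in (0, 1]")
        if self.step <= 0:
            raise ValidationError("step must be positive")


@dataclass
class RankedFeatures:
    """Full feature ranking (best first) with the per-iteration criterion trace."""

    ranking: np.ndarray
    criteria_trace: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        self.ranking = np.asarray(self.ranking, dtype=int)
        d = len(self.ranking)
        if sorted(self.ranking.tolist()) != list(range(d)):
            raise ValidationError("ranking must be a permutation of 0..D-1")


def _dj_criteria(X: np.ndarray, y: np.ndarray, params: RfeParams) -> np.ndarray:
    """DJ(f) for every column of X under the RFE SVM."""
    kernel = params.kernel_type
    svc = SVC(kernel=kernel, C=params.rfe_C, gamma=params.rfe_gamma)
    svc.fit(X, y)
    sv = X[svc.support_]
    a = svc.dual_coef_.ravel()
    d = X.shape[1]
    if kernel == "linear":
        # DJ(f) reduces to w_f^2 / 2 for the linear kernel
        w = a @ sv
        return 0.5 * w**2
    gamma = params.rfe_gamma
    sq = ((sv[:, None, :] - sv[None, :, :]) ** 2) if sv.shape[0] * sv.shape[0] * d < 2e7 else None
    K = np.exp(-gamma * (sq.sum(axis=2) if sq is not None else _sqdist(sv)))
    aKa = a @ K @ a
    out = np.empty(d)
    aK = a[:, None] * K  # reuse: a' (K*E_f) a = sum a_i a_j K_ij exp(g d_f^2)
    for f in range(d):
        df2 = (sv[:, f][:, None] - sv[:, f][None, :]) ** 2 if sq is None else sq[:, :, f]
        k_minus = np.exp(gamma * df2)  # elementwise K_(-f) = K * exp(g d_f^2)
        out[f] = aKa - float(np.sum(aK * k_minus * a[None, :]))
    return 0.5 * out


def _sqdist(sv: np.ndarray) -> np.ndarray:
    sq = np.sum(sv**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (sv @ sv.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def _correlation_components(X: np.ndarray, r_th: float) -> np.ndarray:
    """Component label per column of X under the |Pearson r| >= r_th graph."""
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
    adj = (np.abs(corr) >= r_th).astype(np.int8)
    np.fill_diagonal(adj, 0)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def svm_rfe_cbr(data: FusedDataset | None, params: RfeParams | None = None,
                X: np.ndarray | None = None, y: np.ndarray | None = None) -> RankedFeatures:
    """Rank all features by recursive elimination with optional CBR.

    Accepts either a :class:`FusedDataset` (whose matrix should already be
    scaled) or raw ``X``/``y`` arrays. Ties on the criterion are broken by
    eliminating the lower column index first.
    """
    if params is None:
        params = RfeParams()
    if data is not None:
        X, y = data.matrix, data.labels
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("SVM-RFE needs both classes present")
    d = X.shape[1]
    if d < 2:
        raise ValidationError("need at least 2 features to rank")
    surviving = list(range(d))
    eliminated: list[int] = []  # worst first
    trace: list[tuple[np.ndarray, np.ndarray]] = []
    while surviving:
        cols = np.array(surviving)
        crit = _dj_criteria(X[:, cols], y, params)
        trace.append((cols.copy(), crit.copy()))
        if params.step < 1:
            n_remove = max(1, int(math.floor(params.step * len(surviving))))
        else:
            n_remove = min(int(params.step), len(surviving))
        # candidates ascending by (criterion, column index): worst first
        order = sorted(range(len(surviving)), key=lambda p: (crit[p], surviving[p]))
        if params.use_cbr and len(surviving) > 1:
            comp = _correlation_components(X[:, cols], params.r_th)
            used: set[int] = set()
            picked: list[int] = []
            for p in order:
                if len(picked) == n_remove:
                    break
                if comp[p] in used:
                    continue  # defer: a correlated sibling already leaves this round
                used.add(int(comp[p]))
                picked.append(p)
            if not picked:
                picked = [order[0]]
        else:
            picked = order[:n_remove]
        for p in sorted(picked, key=lambda p: (crit[p], surviving[p])):
            eliminated.append(surviving[p])
        for p in sorted(picked, reverse=True):
            surviving.pop(p)
    ranking = np.array(eliminated[::-1], dtype=int)
    return RankedFeatures(ranking, trace)


def select_top(ranked: RankedFeatures, n: int) -> np.ndarray:
    """The n best-ranked column indices; nested in n by construction."""
    d = len(ranked.ranking)
    if not (1 <= n <= d):
        raise ValidationError(f"n must be in 1..{d}, got {n}")
    return ranked.ranking[:n].copy()
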