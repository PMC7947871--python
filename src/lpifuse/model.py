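"""RBF-SVM training, grid search and leakage-aware five-fold cross-validation.

The classifier is a support vector machine with a Gaussian RBF kernel; C
and gamma are chosen by grid search over libsvm-style ladders maximising
mean inner-cross-validation AUC. The published optimum (C = 256,
gamma = 0.002) is always a member of the default grids.

Cross-validation treats the interaction network itself as the label
source, so per fold the topology feature block is rebuilt with that fold's
positive edges zeroed: otherwise a test pair's own label would leak into
its feature vector. The scaler, feature ranking, subset-size choice and
grid search are all fitted on training rows only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import lncrna as _ln
from . import protein as _pr
from .evaluation import EvalReport, report_from_scores, roc_pr
from .fusion import (
    FusedDataset,
    MinMax,
    RankedFeatures,
    RfeParams,
    fuse,
    select_top,
    svm_rfe_cbr,
)
from .io import (
    ExpressionTable,
    InteractionNetwork,
    Pssm,
    SequenceRecord,
    ValidationError,
)
from .network import FeatureBlock, PairIndex, build_topology_block

logger = logging.getLogger(__name__)

#: libsvm-style grid ladders (powers of 4) with the published optimum appended.
DEFAULT_C_GRID = tuple(sorted(set(float(2**e) for e in range(-5, 16, 2)) | {256.0}))
DEFAULT_GAMMA_GRID = tuple(sorted(set(float(2**e) for e in range(-15, 4, 2)) | {0.002}))

#: Candidate selected-subset sizes for RFE-based selection ("all" = None).
DEFAULT_N_GRID = (25, 50, 100, 200, 400, None)

ALL_BLOCKS = ("LDNet", "KPSSM", "CTD", "SEQ", "EXPR")


@dataclass(frozen=True)
class SvmConfig:
    C: float = 256.0
    gamma: float = 0.002
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValidationError("C and gamma must be positive")


@dataclass
class CvPlan:
    """Fold plan: stratified, seeded, reproducible."""

    n_folds: int = 5
    seed: int = 0

    def assign(self, labels: np.ndarray) -> np.ndarray:
        """Fold id per row; stratified by label, shuffled with the plan seed."""
        labels = np.asarray(labels, dtype=int)
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        fold = np.empty(len(labels), dtype=int)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
            fold[test_idx] = f
        return fold


def make_pair_dataset(
    net: InteractionNetwork,
    negative_policy: str = "all",
    seed: int = 0,
) -> tuple[list[PairIndex], np.ndarray]:
    """Labeled pair list: positives are edges; negatives are non-edges.

    ``negative_policy="all"`` takes the full complement (heavily imbalanced,
    the realistic setting); ``"balanced"`` draws a seed-reproducible uniform
    sample of non-edges of the same size as the positive set.
    """
    pos = [PairIndex(int(i), int(j)) for i, j in zip(*np.nonzero(net.adjacency))]
    if not pos:
        raise ValidationError("network has no positive pairs")
    neg = [PairIndex(int(i), int(j)) for i, j in zip(*np.nonzero(net.adjacency == 0))]
    if negative_policy == "balanced":
        if len(neg) > len(pos):
            rng = np.random.default_rng(seed)
            sel = rng.choice(len(neg), size=len(pos), replace=False)
            neg = [neg[k] for k in sorted(sel)]
    elif negative_policy != "all":
        raise ValidationError(f"unknown negative_policy {negative_policy!r}")
    pairs = pos + neg
    labels = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    return pairs, labels


# ---------------------------------------------------------------------------
# Node-level feature extraction (everything except topology is pair-independent)

@dataclass
class NodeFeatures:
    """Per-node feature vectors shared across all pairs involving the node."""

    lncrna_seq: dict[str, np.ndarray]  # 35-dim: MI(19) + dinucleotide comp(16)
    lncrna_expr: dict[str, np.ndarray]  # 24-dim expression rows
    protein_kpssm: dict[str, np.ndarray]  # 400*k
    protein_ctd: dict[str, np.ndarray]  # 273


def extract_node_features(
    lncrna_records: Sequence[SequenceRecord],
    pssms: Sequence[Pssm],
    expression: ExpressionTable | None = None,
    k: int = 1,
    epsilon: float = _ln.DEFAULT_EPSILON,
    ctd_table=None,
    log_expression: bool = True,
) -> NodeFeatures:
    """Extract every pair-independent feature once per node.

    Expression rows are log1p-transformed by default: expression values are
    heavy-tailed, and min-max scaling of raw values compresses almost all
    rows into a tiny corner of [0, 1], which starves kernel methods of
    resolution. Set ``log_expression=False`` for raw values.
    """
    seq_feats = {
        r.id: np.concatenate([_ln.mi_block(r, epsilon), _ln.composition_block(r)])
        for r in lncrna_records
    }
    if expression is not None:
        expr_feats = {
            r.id: (np.log1p(row) if log_expression else row)
            for r in lncrna_records
            for row in [_ln.expression_block(r.id, expression)]
        }
    else:
        expr_feats = {r.id: np.zeros(_ln.EXPR_BLOCK_DIM) for r in lncrna_records}
    if ctd_table is None:
        ctd_table = _pr.load_ctd_table()
    kpssm = {p.protein_id: _pr.kpssm_composition(p, k) for p in pssms}
    ctd_feats = {p.protein_id: _pr.ctd_vector(p.sequence, ctd_table) for p in pssms}
    return NodeFeatures(seq_feats, expr_feats, kpssm, ctd_feats)


def _broadcast_block(
    name: str,
    pairs: list[PairIndex],
    ids: list[str],
    table: dict[str, np.ndarray],
    by_lncrna: bool,
) -> FeatureBlock:
    dim = len(next(iter(table.values())))
    mat = np.empty((len(pairs), dim))
    for row, p in enumerate(pairs):
        key = ids[p.i] if by_lncrna else ids[p.j]
        mat[row] = table[key]
    return FeatureBlock(name, pairs, mat, dim)


def assemble_blocks(
    net: InteractionNetwork,
    pairs: list[PairIndex],
    node_features: NodeFeatures,
    blocks: Sequence[str] = ALL_BLOCKS,
    masked_edges: Sequence[PairIndex] = (),
) -> list[FeatureBlock]:
    """Materialise the requested feature blocks for an ordered pair list."""
    out: list[FeatureBlock] = []
    for name in blocks:
        if name == "LDNet":
            out.append(build_topology_block(net, pairs, masked_edges))
        elif name == "KPSSM":
            out.append(_broadcast_block(name, pairs, net.protein_ids,
                                        node_features.protein_kpssm, by_lncrna=False))
        elif name == "CTD":
            out.append(_broadcast_block(name, pairs, net.protein_ids,
                                        node_features.protein_ctd, by_lncrna=False))
        elif name == "SEQ":
            out.append(_broadcast_block(name, pairs, net.lncrna_ids,
                                        node_features.lncrna_seq, by_lncrna=True))
        elif name == "EXPR":
            out.append(_broadcast_block(name, pairs, net.lncrna_ids,
                                        node_features.lncrna_expr, by_lncrna=True))
        else:
            raise ValidationError(f"unknown feature block {name!r}")
    return out


# ---------------------------------------------------------------------------
# Training and model persistence

def train(X: np.ndarray, y: np.ndarray, config: SvmConfig = SvmConfig()) -> SVC:
    """Fit the RBF-SVM on scaled features; exposes decision_function scores."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("training set must contain both classes")
    svc = SVC(kernel=config.kernel, C=config.C, gamma=config.gamma)
    svc.fit(np.asarray(X, dtype=float), y)
    return svc


@dataclass
class ModelBundle:
    """Everything needed to score new pairs: scaler, selected columns, SVM."""

    model: SVC
    scaler: MinMax
    selected: np.ndarray | None
    config: SvmConfig
    blocks: tuple[str, ...]
    version: str = "1"

    def score(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform(X)
        if self.selected is not None:
            Xs = Xs[:, self.selected]
        return self.model.decision_function(Xs)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, directory / "bundle.joblib")

    @staticmethod
    def load(directory: str | Path) -> "ModelBundle":
        return joblib.load(Path(directory) / "bundle.joblib")


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    plan: CvPlan | None = None,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> SvmConfig:
    """Pick (C, gamma) maximising mean inner-CV AUC; ties -> smaller C, then gamma."""
    if not len(C_grid) or not len(gamma_grid):
        raise ValidationError("grids must be non-empty")
    if plan is None:
        plan = CvPlan()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(C_grid) == 1 and len(gamma_grid) == 1:
        return SvmConfig(float(C_grid[0]), float(gamma_grid[0]))
    fold = plan.assign(y)
    best: tuple[float, float, float] | None = None  # (-auc, C, gamma) minimised
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            aucs = []
            for f in range(plan.n_folds):
                tr, te = fold != f, fold == f
                if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                    raise ValidationError("degenerate single-class inner fold")
                svc = SVC(kernel="rbf", C=C, gamma=gamma).fit(X[tr], y[tr])
                _, _, auc, _ = roc_pr(svc.decision_function(X[te]), y[te])
                aucs.append(auc)
            key = (-float(np.mean(aucs)), C, gamma)
            if best is None or key < best:
                best = key
    return SvmConfig(best[1], best[2])


def _choose_subset_size(
    X: np.ndarray,
    y: np.ndarray,
    ranked: RankedFeatures,
    n_grid: Sequence[int | None],
    config: SvmConfig,
    plan: CvPlan,
) -> int:
    """Pick the selected-subset size by inner-CV AUC over a size grid."""
    d = X.shape[1]
    sizes = sorted({d if n is None else min(n, d) for n in n_grid})
    if len(sizes) == 1:
        return sizes[0]
    fold = plan.assign(y)
    best = None
    for n in sizes:
        cols = select_top(ranked, n)
        aucs = []
        for f in range(plan.n_folds):
            tr, te = fold != f, fold == f
            svc = SVC(kernel="rbf", C=config.C, gamma=config.gamma).fit(X[tr][:, cols], y[tr])
            _, _, auc, _ = roc_pr(svc.decision_function(X[te][:, cols]), y[te])
            aucs.append(auc)
        key = (-float(np.mean(aucs)), n)
        if best is None or key < best:
            best = key
    return best[1]


# ---------------------------------------------------------------------------
# Cross-validation

@dataclass
class CvResult:
    fold_reports: list[EvalReport]
    pooled: EvalReport
    fold_assignment: np.ndarray
    pairs: list[PairIndex]
    labels: np.ndarray
    oof_scores: np.ndarray
    fold_configs: list[SvmConfig]
    fold_subset_sizes: list[int | None]


def cross_validate(
    net: InteractionNetwork,
    node_features: NodeFeatures,
    blocks: Sequence[str] = ALL_BLOCKS,
    rfe_params: RfeParams | None = None,
    n_grid: Sequence[int | None] = DEFAULT_N_GRID,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    plan: CvPlan | None = None,
    negative_policy: str = "all",
    inner_folds: int = 5,
) -> CvResult:
    """Leakage-aware k-fold cross-validation of the full pipeline.

    Per fold: the topology block is rebuilt with the fold's positive edges
    masked; the min-max scaler, the (optional) SVM-RFE+CBR ranking with its
    subset-size choice, and the (C, gamma) grid search are fitted on
    training rows only; test rows are scored with the fold's model. Pooled
    curves come from the concatenated out-of-fold scores.
    """
    if plan is None:
        plan = CvPlan()
    pairs, labels = make_pair_dataset(net, negative_policy, plan.seed)
    fold = plan.assign(labels)
    oof = np.empty(len(pairs))
    fold_reports: list[EvalReport] = []
    fold_configs: list[SvmConfig] = []
    fold_sizes: list[int | None] = []
    inner_plan = CvPlan(n_folds=inner_folds, seed=plan.seed + 1)
    for f in range(plan.n_folds):
        te = fold == f
        tr = ~te
        if labels[te].sum() == 0 or labels[tr].sum() == 0:
            raise ValidationError(f"fold {f} has no positive pairs")
        masked = [pairs[k] for k in np.flatnonzero(te & (labels == 1))]
        feature_blocks = assemble_blocks(net, pairs, node_features, blocks, masked)
        fused = fuse(feature_blocks, labels)
        scaler = MinMax().fit(fused.matrix[tr])
        Xtr = scaler.transform(fused.matrix[tr])
        Xte = scaler.transform(fused.matrix[te])
        ytr = labels[tr]
        selected = None
        if rfe_params is not None:
            ranked = svm_rfe_cbr(None, rfe_params, X=Xtr, y=ytr)
            n_sel = _choose_subset_size(Xtr, ytr, ranked, n_grid,
                                        SvmConfig(rfe_params.rfe_C, rfe_params.rfe_gamma),
                                        inner_plan)
            selected = select_top(ranked, n_sel)
            Xtr, Xte = Xtr[:, selected], Xte[:, selected]
        config = grid_search(Xtr, ytr, inner_plan, C_grid, gamma_grid)
        svc = train(Xtr, ytr, config)
        scores = svc.decision_function(Xte)
        oof[te] = scores
        fold_reports.append(report_from_scores(scores, labels[te]))
        fold_configs.append(config)
        fold_sizes.append(None if selected is None else len(selected))
        logger.info("fold %d: C=%g gamma=%g AUC=%.4f", f, config.C, config.gamma,
                    fold_reports[-1].auc if fold_reports[-1].auc is not None else float("nan"))
    pooled = report_from_scores(oof, labels)
    return CvResult(fold_reports, pooled, fold, pairs, labels, oof, fold_configs, fold_sizes)
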