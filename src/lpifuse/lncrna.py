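"""lncRNA sequence descriptors: k-gram mutual information, base composition,
and expression-profile lookup.

Probabilities of 1-, 2- and 3-grams are estimated from overlapping windows
with additive smoothing:

    p(x)     = (N_x   + eps) / L
    p(x, y)  = (N_xy  + eps) / (L - 1)
    p(x,y,z) = (N_xyz + eps) / (L - 2)

where eps > 0 guards against zero counts. Windows containing an ambiguous
base (N) are skipped and the denominators use the effective window counts,
so the distributions still normalise at eps = 0.

From these the per-symbol (not alphabet-summed) information quantities are

    MI(x, y)    = p(x,y) * log2[ p(x,y) / (p(x) p(y)) ]
    H(x | z)    = -[p(x,z)/p(z)] * log2[ p(x,z)/p(z) ]
    H(x | y,z)  = -[p(x,y,z)/p(y,z)] * log2[ p(x,y,z)/p(y,z) ]
    MI(x, y|z)  = H(x|z) - H(x|y,z)
    MI(x, y, z) = MI(x,y) - MI(x,y|z)

MI(x, y) uses symmetrised pair probabilities (the average of the ordered
dinucleotide counts N_xy and N_yx for x != y) so that MI(x,y) = MI(y,x)
holds exactly while the pair distribution stays normalised.

Logarithms are base 2 (bits) throughout; an SVM with per-column rescaling
is indifferent to the base.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product

import numpy as np

from .io import ExpressionTable, SequenceRecord, ValidationError, N_TISSUES

logger = logging.getLogger(__name__)

BASES = "ACGT"
DEFAULT_EPSILON = 1e-6

#: Alphabetical layout of the 16 ordered dinucleotides (AA, AC, ..., TT).
DINUCLEOTIDES = tuple(a + b for a, b in product(BASES, repeat=2))
TRINUCLEOTIDES = tuple(a + b + c for a, b, c in product(BASES, repeat=3))

MI_BLOCK_DIM = 19
COMP_BLOCK_DIM = 16
SEQ_BLOCK_DIM = MI_BLOCK_DIM + COMP_BLOCK_DIM  # 35
EXPR_BLOCK_DIM = N_TISSUES  # 24


@dataclass
class KgramModel:
    """Smoothed 1/2/3-gram occurrence model of one nucleotide sequence.

    ``n1``/``n2``/``n3`` are raw overlapping-window counts (windows with an
    ambiguous base excluded); ``d1``/``d2``/``d3`` the corresponding
    effective window totals (L, L-1, L-2 for an unambiguous sequence).
    """

    n1: dict[str, int]
    n2: dict[str, int]
    n3: dict[str, int]
    d1: int
    d2: int
    d3: int
    epsilon: float

    def p1(self, x: str) -> float:
        return (self.n1[x] + self.epsilon) / self.d1

    def p2(self, xy: str) -> float:
        """Ordered dinucleotide probability."""
        return (self.n2[xy] + self.epsilon) / self.d2

    def p2_sym(self, xy: str) -> float:
        """Symmetrised dinucleotide probability: average of both orders."""
        x, y = xy
        if x == y:
            return self.p2(xy)
        n = 0.5 * (self.n2[x + y] + self.n2[y + x])
        return (n + self.epsilon) / self.d2

    def p3(self, xyz: str) -> float:
        return (self.n3[xyz] + self.epsilon) / self.d3


def kgram_probs(seq: SequenceRecord | str, epsilon: float = DEFAULT_EPSILON) -> KgramModel:
    """Count overlapping 1/2/3-grams and build the smoothed probability model."""
    if epsilon <= 0:
        raise ValidationError("epsilon must be > 0")
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq.upper().replace("U", "T")
    n1 = {b: 0 for b in BASES}
    n2 = {d: 0 for d in DINUCLEOTIDES}
    n3 = {t: 0 for t in TRINUCLEOTIDES}
    d1 = d2 = d3 = 0
    for i, ch in enumerate(s):
        if ch in n1:
            n1[ch] += 1
            d1 += 1
        di = s[i : i + 2]
        if len(di) == 2 and di in n2:
            n2[di] += 1
            d2 += 1
        tri = s[i : i + 3]
        if len(tri) == 3 and tri in n3:
            n3[tri] += 1
            d3 += 1
    if d3 < 1 or d1 < 3:
        raise ValidationError("sequence too short after dropping ambiguous windows (need length >= 3)")
    return KgramModel(n1, n2, n3, d1, d2, d3, epsilon)


def _plogp(p: float) -> float:
    return -p * math.log2(p)


def mi_pair(model: KgramModel, x: str, y: str) -> float:
    """Pairwise per-symbol mutual information MI(x, y), in bits; symmetric in x, y."""
    pxy = model.p2_sym(x + y)
    return pxy * math.log2(pxy / (model.p1(x) * model.p1(y)))


def h_symbol(model: KgramModel, x: str) -> float:
    """Per-symbol entropy term H(x) = -p(x) log2 p(x)."""
    return _plogp(model.p1(x))


def h_cond_pair(model: KgramModel, x: str, z: str) -> float:
    """H(x|z) = -[p(x,z)/p(z)] log2 [p(x,z)/p(z)] (per-symbol form)."""
    r = model.p2(x + z) / model.p1(z)
    return _plogp(r)


def h_cond_triplet(model: KgramModel, x: str, y: str, z: str) -> float:
    """H(x|y,z) = -[p(x,y,z)/p(y,z)] log2 [p(x,y,z)/p(y,z)] (per-symbol form)."""
    r = model.p3(x + y + z) / model.p2(y + z)
    return _plogp(r)


def mi_cond(model: KgramModel, x: str, y: str, z: str) -> float:
    """Conditional mutual information MI(x, y | z) = H(x|z) - H(x|y,z)."""
    return h_cond_pair(model, x, z) - h_cond_triplet(model, x, y, z)


def mi_triplet(model: KgramModel, x: str, y: str, z: str) -> float:
    """Triplet mutual information MI(x, y, z) = MI(x, y) - MI(x, y | z)."""
    return mi_pair(model, x, y) - mi_cond(model, x, y, z)


def mi_block(seq: SequenceRecord | str, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """The 19-dim mutual-information block.

    Entries 0-15: MI(x, y) for the 16 ordered base pairs in alphabetical
    order (AA, AC, ..., TT). Entries 16-18: mean, min and max of
    MI(x, y, z) over all 64 ordered base triplets.
    """
    model = kgram_probs(seq, epsilon)
    pairs = [mi_pair(model, d[0], d[1]) for d in DINUCLEOTIDES]
    trips = [mi_triplet(model, t[0], t[1], t[2]) for t in TRINUCLEOTIDES]
    return np.array(pairs + [float(np.mean(trips)), min(trips), max(trips)])


def composition_block(seq: SequenceRecord | str, include_mono: bool = False) -> np.ndarray:
    """Dinucleotide composition: overlapping counts / (L - 1), alphabetical order.

    With ``include_mono`` the 4 mononucleotide fractions are prepended
    (20-dim variant); the default is the 16-dim dinucleotide block.
    Ambiguous windows are excluded from both numerator and denominator.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq.upper().replace("U", "T")
    if len(s) < 2:
        raise ValidationError("composition needs sequence length >= 2")
    n2 = {d: 0 for d in DINUCLEOTIDES}
    d2 = 0
    for i in range(len(s) - 1):
        w = s[i : i + 2]
        if w in n2:
            n2[w] += 1
            d2 += 1
    if d2 == 0:
        raise ValidationError("no unambiguous dinucleotide windows")
    di = np.array([n2[d] for d in DINUCLEOTIDES], dtype=float) / d2
    if not include_mono:
        return di
    n1 = np.array([s.count(b) for b in BASES], dtype=float)
    if n1.sum() == 0:
        raise ValidationError("no unambiguous bases")
    return np.concatenate([n1 / n1.sum(), di])


def expression_block(lncrna_id: str, table: ExpressionTable) -> np.ndarray:
    """The lncRNA's 24-tissue expression row; zeros (with a warning) if absent."""
    row = table.row(lncrna_id)
    if row is None:
        logger.warning("lncRNA %r absent from expression table; using zeros", lncrna_id)
        return np.zeros(EXPR_BLOCK_DIM)
    return row.astype(float).copy()


def lncrna_feature_vector(
    seq: SequenceRecord,
    table: ExpressionTable | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """MI block + composition block (35), plus the expression row (59) if a table is given."""
    parts = [mi_block(seq, epsilon), composition_block(seq)]
    if table is not None:
        parts.append(expression_block(seq.id, table))
    return np.concatenate(parts)
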