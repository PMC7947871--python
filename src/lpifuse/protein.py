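"""Protein descriptors: K-PSSM-composition and CTD.

K-PSSM-composition summarises a protein's position-specific scoring matrix
by splitting its rows into k contiguous segments and, within each segment,
summing the rows that belong to each of the 20 residue types. Each segment
yields a 20x20 = 400-vector; the full descriptor has 400*k entries. With
the default k=1 it reduces to the classic PSSM-composition.

CTD (composition/transition/distribution) maps the 20 amino acids into 3
groups under each of 13 physicochemical properties and reports, per
property: the fraction of residues in each group (C, 3 values), the
fraction of adjacent residue pairs whose groups differ, per unordered group
pair (T, 3 values), and the relative sequence positions (percent of length)
of the first, 25%, 50%, 75% and last residue of each group (D, 15 values).
Total: 13 * (3 + 3 + 15) = 273 dimensions.

The grouping table ships as ``data/ctd_groups.tsv`` (the 13-property set
popularised by the iFeature toolkit: seven hydrophobicity scales plus
normalised van der Waals volume, polarity, polarizability, charge,
secondary structure and solvent accessibility) and can be replaced by any
table with the same layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .io import Pssm, SequenceRecord, ValidationError, PSSM_RESIDUE_ORDER

KPSSM_DIM_PER_SEGMENT = 400
CTD_DIM = 273
N_CTD_PROPERTIES = 13

_D_QUANTILES = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class CtdPropertyTable:
    """13 physicochemical properties, each partitioning the 20 residues into 3 groups."""

    property_names: tuple[str, ...]
    groupings: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if len(self.property_names) != N_CTD_PROPERTIES:
            raise ValidationError(
                f"expected {N_CTD_PROPERTIES} CTD properties, got {len(self.property_names)}"
            )
        for name, groups in zip(self.property_names, self.groupings):
            if len(groups) != 3:
                raise ValidationError(f"property {name!r}: expected 3 groups")
            merged = "".join(groups)
            if sorted(merged) != sorted(PSSM_RESIDUE_ORDER):
                raise ValidationError(
                    f"property {name!r}: groups must partition the 20 residues exactly"
                )


def load_ctd_table(path: str | Path | None = None) -> CtdPropertyTable:
    """Load a CTD grouping table; defaults to the packaged 13-property set."""
    if path is None:
        source = resources.files("lpifuse").joinpath("data/ctd_groups.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    names: list[str] = []
    groups: list[tuple[str, str, str]] = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for line in lines[1:]:  # skip header
        cells = line.split("\t")
        if len(cells) != 4:
            raise ValidationError(f"CTD table row needs 4 columns: {line!r}")
        names.append(cells[0])
        groups.append((cells[1], cells[2], cells[3]))
    return CtdPropertyTable(tuple(names), tuple(groups))


def kpssm_composition(pssm: Pssm, k: int = 1) -> np.ndarray:
    """K-PSSM-composition descriptor of length 400*k.

    Rows are split into k contiguous segments. Within a segment, for each
    residue type (in PSI-BLAST column order) the rows at positions holding
    that residue are summed, giving a 20-vector; the 20 per-residue vectors
    concatenate to 400 values per segment, segments in sequence order.
    """
    if k < 1:
        raise ValidationError("k must be a positive integer")
    if k > len(pssm):
        raise ValidationError(f"k={k} exceeds sequence length {len(pssm)}")
    order = pssm.residue_order
    res_index = {aa: t for t, aa in enumerate(order)}
    out = np.zeros(KPSSM_DIM_PER_SEGMENT * k)
    row_segments = np.array_split(np.arange(len(pssm)), k)
    for seg, rows in enumerate(row_segments):
        base = seg * KPSSM_DIM_PER_SEGMENT
        for r in rows:
            t = res_index.get(pssm.sequence[r])
            if t is None:  # non-standard residue (e.g. X): contributes nowhere
                continue
            out[base + 20 * t : base + 20 * (t + 1)] += pssm.scores[r]
    return out


def _group_sequence(seq: str, groups: tuple[str, str, str]) -> np.ndarray:
    """Map residues to group labels 0/1/2; unknown residues must be gone already."""
    lookup = {}
    for g, members in enumerate(groups):
        for aa in members:
            lookup[aa] = g
    return np.array([lookup[aa] for aa in seq], dtype=np.int8)


def ctd(
    seq: SequenceRecord | str, table: CtdPropertyTable | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Composition, transition and distribution descriptors.

    Returns ``(C, T, D)`` of lengths 39, 39 and 195. The residue X is
    dropped before computation. C and T are fractions in [0, 1]; D entries
    are percent positions in [0, 100]. Layout: properties in table order;
    within a property, groups 1..3 for C, unordered group pairs
    (1,2), (1,3), (2,3) for T, and per group the five quantile positions
    for D.
    """
    if table is None:
        table = load_ctd_table()
    raw = seq.sequence if isinstance(seq, SequenceRecord) else seq
    s = raw.upper().replace("X", "")
    if len(s) < 2:
        raise ValidationError("CTD needs at least 2 standard residues after dropping X")
    L = len(s)
    c_out = np.zeros(3 * N_CTD_PROPERTIES)
    t_out = np.zeros(3 * N_CTD_PROPERTIES)
    d_out = np.zeros(15 * N_CTD_PROPERTIES)
    for p, groups in enumerate(table.groupings):
        labels = _group_sequence(s, groups)
        # C: group fractions
        for g in range(3):
            c_out[3 * p + g] = np.count_nonzero(labels == g) / L
        # T: unordered transition fractions over the L-1 adjacent pairs
        a, b = labels[:-1], labels[1:]
        for t_idx, (r, q) in enumerate(((0, 1), (0, 2), (1, 2))):
            t_out[3 * p + t_idx] = np.count_nonzero(
                ((a == r) & (b == q)) | ((a == q) & (b == r))
            ) / (L - 1)
        # D: percent positions of the 1st/25%/50%/75%/100% occurrence per group
        for g in range(3):
            positions = np.flatnonzero(labels == g) + 1  # 1-based
            base = 15 * p + 5 * g
            if positions.size == 0:
                continue  # absent group: five zeros
            n = positions.size
            for qi, q in enumerate(_D_QUANTILES):
                rank = max(1, math.ceil(q * n))
                d_out[base + qi] = 100.0 * positions[rank - 1] / L
    return c_out, t_out, d_out


def ctd_vector(seq: SequenceRecord | str, table: CtdPropertyTable | None = None) -> np.ndarray:
    """The full 273-dim CTD vector: C block, then T block, then D block."""
    c, t, d = ctd(seq, table)
    return np.concatenate([c, t, d])


def protein_feature_vector(pssm: Pssm, k: int = 1, table: CtdPropertyTable | None = None) -> np.ndarray:
    """K-PSSM-composition followed by CTD of the PSSM's own sequence (400*k + 273)."""
    return np.concatenate([kpssm_composition(pssm, k), ctd_vector(pssm.sequence, table)])
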