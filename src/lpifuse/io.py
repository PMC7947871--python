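"""Readers, writers and validated containers for every file the pipeline touches.

Four external formats are supported:

* FASTA for lncRNA (nucleotide) and protein sequences, via Biopython;
* PSI-BLAST ASCII PSSM (the ``-out_ascii_pssm`` dialect) — only the first
  block of 20 integer log-odds columns is used, the percentage block is
  ignored;
* two-column TSV of (lncRNA_id, protein_id) interaction pairs;
* TSV expression tables with one row per lncRNA and 24 tissue columns.

All readers validate aggressively and name the offending record or line in
their error messages; every reader round-trips with its paired writer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

logger = logging.getLogger(__name__)

#: PSI-BLAST column order of the 20 standard amino acids.
PSSM_RESIDUE_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Number of tissue/cell-type columns in an expression profile.
N_TISSUES = 24

_NUCLEOTIDE_ALPHABET = set("ACGTUN")
_PROTEIN_ALPHABET = set(PSSM_RESIDUE_ORDER) | {"X"}


class ValidationError(ValueError):
    """Raised when an input file or container violates a format contract."""


class Alphabet(str, Enum):
    nucleotide = "nucleotide"
    protein = "protein"


@dataclass(frozen=True)
class SequenceRecord:
    """A single validated sequence.

    Nucleotide sequences are canonicalized on construction: upper-cased and
    with U replaced by T. Protein sequences are upper-cased only.
    """

    id: str
    sequence: str
    alphabet: Alphabet

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if self.alphabet == Alphabet.nucleotide:
            seq = seq.replace("U", "T")
            bad = set(seq) - {"A", "C", "G", "T", "N"}
        else:
            bad = set(seq) - _PROTEIN_ALPHABET
        if not seq:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal residues {sorted(bad)} "
                f"for alphabet {self.alphabet.value}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Pssm:
    """Position-specific scoring matrix for one protein.

    ``scores`` holds the first (log-odds) block of a PSI-BLAST ASCII PSSM:
    one row per sequence position, 20 columns in :data:`PSSM_RESIDUE_ORDER`.
    ``sequence`` is the per-position residue column of the file, needed to
    group rows by residue type downstream.
    """

    protein_id: str
    scores: np.ndarray
    sequence: str
    residue_order: str = PSSM_RESIDUE_ORDER

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValidationError(
                f"PSSM {self.protein_id!r}: expected L x 20 scores, "
                f"got shape {self.scores.shape}"
            )
        if len(self.sequence) != self.scores.shape[0]:
            raise ValidationError(
                f"PSSM {self.protein_id!r}: {self.scores.shape[0]} score rows "
                f"but sequence length {len(self.sequence)}"
            )
        if sorted(self.residue_order) != sorted(PSSM_RESIDUE_ORDER):
            raise ValidationError("residue_order must permute the 20 standard residues")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class ExpressionTable:
    """Expression of lncRNAs across 24 human tissues/cell types."""

    lncrna_ids: list[str]
    values: np.ndarray
    tissue_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_TISSUES:
            raise ValidationError(
                f"expression table must have {N_TISSUES} columns, "
                f"got shape {self.values.shape}"
            )
        if len(self.lncrna_ids) != self.values.shape[0]:
            raise ValidationError("row count does not match number of lncRNA ids")
        if len(self.tissue_names) != N_TISSUES:
            raise ValidationError(f"expected {N_TISSUES} tissue names")
        if len(set(self.lncrna_ids)) != len(self.lncrna_ids):
            raise ValidationError("duplicate lncRNA ids in expression table")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("expression values must be finite and non-negative")

    def row(self, lncrna_id: str) -> np.ndarray | None:
        try:
            return self.values[self.lncrna_ids.index(lncrna_id)]
        except ValueError:
            return None


@dataclass
class InteractionNetwork:
    """Bipartite lncRNA x protein interaction network.

    ``adjacency[i, j] == 1`` iff lncRNA ``lncrna_ids[i]`` interacts with
    protein ``protein_ids[j]``.
    """

    lncrna_ids: list[str]
    protein_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        n, m = len(self.lncrna_ids), len(self.protein_ids)
        if self.adjacency.shape != (n, m):
            raise ValidationError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"{n} lncRNAs x {m} proteins"
            )
        if len(set(self.lncrna_ids)) != n or len(set(self.protein_ids)) != m:
            raise ValidationError("duplicate node identifiers in network")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        if n < 2 or m < 2:
            raise ValidationError("network needs at least 2 lncRNAs and 2 proteins")

    @property
    def n_lncrna(self) -> int:
        return len(self.lncrna_ids)

    @property
    def n_protein(self) -> int:
        return len(self.protein_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, alphabet: Alphabet | str) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Nucleotide records are canonicalized (upper case, U -> T). Duplicate
    identifiers or illegal residues raise :class:`ValidationError` naming
    the offending record.
    """
    alphabet = Alphabet(alphabet)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), alphabet))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Sequence[SequenceRecord]) -> None:
    bio = [BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM

def read_pssm(path: str | Path, protein_id: str | None = None) -> Pssm:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first block of 20 integer columns (position-specific log-odds)
    is kept. Data rows are recognised as ``<position> <residue> <20+ ints>``;
    a malformed row raises :class:`ValidationError` with its line number.
    """
    path = Path(path)
    scores: list[list[float]] = []
    residues: list[str] = []
    expected_pos = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if not tokens[0].lstrip("-").isdigit():
                continue  # header / footer lines
            if int(tokens[0]) != expected_pos:
                continue  # e.g. lambda/K footer starting with a number
            if len(tokens) < 2 or len(tokens[1]) != 1 or not tokens[1].isalpha():
                raise ValidationError(f"{path}:{lineno}: malformed PSSM row")
            cells = tokens[2:22]
            if len(cells) < 20:
                raise ValidationError(
                    f"{path}:{lineno}: expected 20 log-odds columns, got {len(cells)}"
                )
            try:
                scores.append([float(c) for c in cells])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-numeric cell ({exc})")
            residues.append(tokens[1].upper())
            expected_pos += 1
    if not scores:
        raise ValidationError(f"{path}: no PSSM data rows found")
    return Pssm(protein_id or path.stem, np.array(scores), "".join(residues))


def write_pssm(path: str | Path, pssm: Pssm) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect (log-odds block only)."""
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(PSSM_RESIDUE_ORDER) + "\n")
        for pos, (res, row) in enumerate(zip(pssm.sequence, pssm.scores), start=1):
            cells = " ".join(f"{int(round(v)):4d}" for v in row)
            fh.write(f"{pos:5d} {res} {cells}\n")


# ---------------------------------------------------------------------------
# Interactions

def read_interactions(
    path: str | Path,
    lncrna_records: Sequence[SequenceRecord],
    protein_records: Sequence[SequenceRecord],
    delimiter: str = "\t",
) -> tuple[InteractionNetwork, int]:
    """Read (lncRNA_id, protein_id) pairs into an :class:`InteractionNetwork`.

    Pairs referencing an identifier with no sequence record are dropped and
    counted (nodes without sequence information cannot be featurized);
    duplicate pair lines collapse to a single edge with a logged warning.

    Returns the network and the number of dropped pairs.
    """
    lnc_ids = [r.id for r in lncrna_records]
    pro_ids = [r.id for r in protein_records]
    lnc_set, pro_set = set(lnc_ids), set(pro_ids)
    pairs: list[tuple[str, str]] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: expected two columns")
            lnc, pro = parts[0].strip(), parts[1].strip()
            if lnc not in lnc_set or pro not in pro_set:
                dropped += 1
                continue
            pairs.append((lnc, pro))
    unique = set(pairs)
    if len(unique) < len(pairs):
        logger.warning(
            "%s: %d duplicate interaction lines collapsed", path, len(pairs) - len(unique)
        )
    if not unique:
        raise ValidationError(f"{path}: no valid interaction pairs")
    # keep only nodes participating in at least one valid pair, in record order
    used_lnc = {l for l, _ in unique}
    used_pro = {p for _, p in unique}
    kept_lnc = [i for i in lnc_ids if i in used_lnc]
    kept_pro = [i for i in pro_ids if i in used_pro]
    li = {name: k for k, name in enumerate(kept_lnc)}
    pi = {name: k for k, name in enumerate(kept_pro)}
    adj = np.zeros((len(kept_lnc), len(kept_pro)), dtype=np.int8)
    for l, p in unique:
        adj[li[l], pi[p]] = 1
    return InteractionNetwork(kept_lnc, kept_pro, adj), dropped


def write_interactions(
    path: str | Path, net: InteractionNetwork, delimiter: str = "\t"
) -> None:
    with open(path, "w") as fh:
        for i, j in zip(*np.nonzero(net.adjacency)):
            fh.write(f"{net.lncrna_ids[i]}{delimiter}{net.protein_ids[j]}\n")


def filter_network(net: InteractionNetwork) -> tuple[InteractionNetwork, dict[str, int]]:
    """Iteratively drop degree-<=1 nodes until a fixed point.

    lncRNAs interacting with at most one protein (and proteins with at most
    one lncRNA) carry little correlation structure and are removed; removal
    is repeated because dropping a node can push its neighbours to degree 1.

    Returns the filtered network and removal counts
    ``{"lncrna_removed": ..., "protein_removed": ...}``.
    Raises :class:`ValidationError` if nothing survives.
    """
    adj = net.adjacency.copy()
    lnc_keep = np.arange(adj.shape[0])
    pro_keep = np.arange(adj.shape[1])
    while True:
        lnc_deg = adj.sum(axis=1)
        pro_deg = adj.sum(axis=0)
        lnc_mask = lnc_deg >= 2
        pro_mask = pro_deg >= 2
        if lnc_mask.all() and pro_mask.all():
            break
        adj = adj[lnc_mask][:, pro_mask]
        lnc_keep = lnc_keep[lnc_mask]
        pro_keep = pro_keep[pro_mask]
        if adj.size == 0:
            break
    removed = {
        "lncrna_removed": net.n_lncrna - len(lnc_keep),
        "protein_removed": net.n_protein - len(pro_keep),
    }
    if adj.size == 0 or len(lnc_keep) < 2 or len(pro_keep) < 2:
        raise ValidationError("network empty (or degenerate) after degree filtering")
    filtered = InteractionNetwork(
        [net.lncrna_ids[i] for i in lnc_keep],
        [net.protein_ids[j] for j in pro_keep],
        adj,
    )
    return filtered, removed


# ---------------------------------------------------------------------------
# Expression table

def read_expression(path: str | Path, delimiter: str = "\t") -> ExpressionTable:
    """Read a TSV expression table: header ``id <24 tissue names>``."""
    import pandas as pd

    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[1] != N_TISSUES:
        raise ValidationError(
            f"{path}: expected {N_TISSUES} tissue columns, found {df.shape[1]}"
        )
    return ExpressionTable(
        [str(i) for i in df.index], df.to_numpy(dtype=float), [str(c) for c in df.columns]
    )


def write_expression(path: str | Path, table: ExpressionTable, delimiter: str = "\t") -> None:
    import pandas as pd

    df = pd.DataFrame(table.values, index=table.lncrna_ids, columns=table.tissue_names)
    df.to_csv(path, sep=delimiter, index_label="lncrna_id")


# ---------------------------------------------------------------------------
# Feature matrices

def write_feature_matrix(
    path: str | Path,
    matrix: np.ndarray,
    feature_names: Sequence[str],
    row_names: Sequence[str],
    delimiter: str = "\t",
) -> None:
    """Persist a feature matrix as TSV with block-qualified column names."""
    import pandas as pd

    pd.DataFrame(np.asarray(matrix), index=list(row_names), columns=list(feature_names)).to_csv(
        path, sep=delimiter, index_label="pair"
    )


def read_feature_matrix(path: str | Path, delimiter: str = "\t"):
    import pandas as pd

    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return df.to_numpy(dtype=float), list(df.columns), [str(i) for i in df.index]
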