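"""Delimited-text readers and writers for the network matrices.

Similarity matrices travel as labeled square TSV/CSV tables (first row and
first column are entity names); associations travel as two-column edge
lists (miRNA name, disease name).  The delimiter is auto-detected between
tab and comma.  No binary formats.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import AssociationMatrix, Hyperparameters, SimilarityMatrix

logger = logging.getLogger(__name__)


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_similarity_matrix(path, role: str = "entity") -> SimilarityMatrix:
    """Read a labeled square similarity matrix from TSV/CSV.

    Validation (square shape, [0, 1] range, symmetry, duplicate labels) is
    performed by the :class:`SimilarityMatrix` constructor.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    if list(df.index) != list(df.columns):
        if len(df.index) != len(df.columns):
            raise ValueError(f"{path}: similarity matrix is not square")
        raise ValueError(f"{path}: row labels differ from column labels")
    return SimilarityMatrix([str(x) for x in df.index], df.to_numpy(dtype=float), role=role)


def write_similarity_matrix(path, sim: SimilarityMatrix, sep: str = "\t") -> None:
    df = pd.DataFrame(sim.values, index=sim.labels, columns=sim.labels)
    df.to_csv(Path(path), sep=sep)


def read_association_list(
    path, mirna_labels: Sequence[str], disease_labels: Sequence[str]
) -> AssociationMatrix:
    """Build the binary association matrix from a 2-column edge list.

    Unknown names raise; duplicate edges collapse to a single 1 with a
    logged warning (per-publication duplicates are common in HMDD dumps);
    an empty file yields the all-zero matrix.
    """
    path = Path(path)
    mirna_index = {name: i for i, name in enumerate(mirna_labels)}
    disease_index = {name: j for j, name in enumerate(disease_labels)}
    values = np.zeros((len(mirna_labels), len(disease_labels)))
    n_dup = 0
    try:
        df = pd.read_csv(path, sep=_detect_sep(path), header=None, dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=[0, 1])
    if len(df.columns) not in (0, 2) and len(df):
        raise ValueError(f"{path}: expected 2 columns, found {len(df.columns)}")
    for row_number, (mirna, disease) in enumerate(df.itertuples(index=False), start=1):
        if mirna not in mirna_index:
            raise ValueError(f"{path}, line {row_number}: unknown miRNA {mirna!r}")
        if disease not in disease_index:
            raise ValueError(f"{path}, line {row_number}: unknown disease {disease!r}")
        i, j = mirna_index[mirna], disease_index[disease]
        if values[i, j] == 1:
            n_dup += 1
        values[i, j] = 1.0
    if n_dup:
        logger.warning("%s: collapsed %d duplicate association edge(s)", path, n_dup)
    return AssociationMatrix(list(mirna_labels), list(disease_labels), values)


def write_association_list(path, A: AssociationMatrix, sep: str = "\t") -> None:
    """Write the 1-entries of A as a 2-column edge list (row-major order)."""
    with open(Path(path), "w") as fh:
        for i, j in A.positive_pairs():
            fh.write(f"{A.mirna_labels[i]}{sep}{A.disease_labels[j]}\n")


def write_ranked_candidates(path, ranking, disease: str, sep: str = "\t") -> None:
    """Write an ordered (miRNA, score) list as rank / miRNA / score rows."""
    with open(Path(path), "w") as fh:
        fh.write(sep.join(["rank", "miRNA", "score"]) + "\n")
        for rank, (name, score) in enumerate(ranking, start=1):
            if not np.isfinite(score):
                raise ValueError(f"non-finite score for {name!r}")
            fh.write(f"{rank}{sep}{name}{sep}{score:.10g}\n")
    logger.info("wrote %d ranked candidates for %s to %s", len(list(ranking)), disease, path)


def write_score_matrix(path, U: np.ndarray, A: AssociationMatrix, sep: str = "\t") -> None:
    """Write the score matrix U as a labeled table (miRNAs x diseases)."""
    pd.DataFrame(U, index=A.mirna_labels, columns=A.disease_labels).to_csv(Path(path), sep=sep)


def read_score_matrix(path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_detect_sep(path), index_col=0)


def load_config(path) -> Hyperparameters:
    """Load hyperparameters from a YAML mapping (key ``lambda`` maps to lam)."""
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return Hyperparameters.from_dict(data)


def save_config(path, p: Hyperparameters) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(p.to_dict(), fh, sort_keys=True)
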