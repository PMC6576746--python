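"""Readers and writers for the toolkit's interchange formats.

Tabular inputs are delimited text (TSV/CSV, delimiter inferred from the
extension); sparse matrices travel either as Matrix Market coordinate files
(1-based, per that format's standard) with companion index files (one key
per line) or as TSV triples with string keys.  Reports are TSV or JSON.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .activity import ActivityRecord, InteractionMatrix
from .doseresponse import DoseResponseCurve
from .screen import DockingRecord, ImputationNetwork, SiteSimilarityHit
from .solver import FactorModel, SimilarityGraph

logger = logging.getLogger(__name__)

__all__ = [
    "read_activity_table",
    "read_site_hits",
    "read_docking_table",
    "read_sparse_triples",
    "read_similarity_graph",
    "write_interaction_matrix",
    "read_interaction_matrix",
    "write_imputation_network",
    "read_imputation_network",
    "read_dose_response",
    "read_expression",
    "read_activity_areas",
    "read_gmt",
    "write_report",
    "write_factor_model",
]


def _sep(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_activity_table(path: str) -> list[ActivityRecord]:
    """Activity records from a delimited table with columns chemical_key,
    protein_key, measure, value and optional concentration, source,
    confidence."""
    df = pd.read_csv(path, sep=_sep(path))
    records = []
    for _, row in df.iterrows():
        conc = row.get("concentration")
        conf = row.get("confidence")
        records.append(
            ActivityRecord(
                chemical_key=str(row["chemical_key"]),
                protein_key=str(row["protein_key"]),
                measure=str(row["measure"]),
                value=float(row["value"]),
                concentration=None if pd.isna(conc) else float(conc),
                source=str(row.get("source", "") or ""),
                confidence=None if conf is None or pd.isna(conf) else int(conf),
            )
        )
    return records


def read_site_hits(path: str) -> list[SiteSimilarityHit]:
    df = pd.read_csv(path, sep=_sep(path))
    return [
        SiteSimilarityHit(
            template_id=str(r["template_id"]),
            candidate_structure=str(r["candidate_structure"]),
            protein_key=str(r["protein_key"]),
            p_value=float(r["p_value"]),
        )
        for _, r in df.iterrows()
    ]


def read_docking_table(path: str) -> list[DockingRecord]:
    df = pd.read_csv(path, sep=_sep(path))
    return [
        DockingRecord(
            protein_key=str(r["protein_key"]),
            chemical_key=str(r["chemical_key"]),
            score=float(r["score"]),
        )
        for _, r in df.iterrows()
    ]


def _is_matrix_market(path: str) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("%%MatrixMarket")


def read_sparse_triples(
    path: str, shape: Optional[tuple[int, int]] = None
) -> tuple[sp.csr_matrix, Optional[list[str]], Optional[list[str]]]:
    """Sparse matrix from a Matrix Market file or a key-triple TSV.

    Matrix Market files return ``(matrix, None, None)``; TSV triples
    (row_key, col_key, value) return the matrix together with the sorted
    row/column key indices.
    """
    if _is_matrix_market(path):
        return sp.csr_matrix(mmread(path)), None, None
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3+ tab-separated fields")
            try:
                vals.append(float(parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad value {parts[2]!r}") from exc
            rows.append(parts[0])
            cols.append(parts[1])
    row_index = sorted(set(rows))
    col_index = sorted(set(cols))
    rpos = {k: i for i, k in enumerate(row_index)}
    cpos = {k: i for i, k in enumerate(col_index)}
    mat = sp.csr_matrix(
        (vals, ([rpos[r] for r in rows], [cpos[c] for c in cols])),
        shape=shape or (len(row_index), len(col_index)),
    )
    return mat, row_index, col_index


def read_similarity_graph(path: str) -> SimilarityGraph:
    """Similarity graph from triples over one key set; asymmetric input is
    symmetrized (with a warning) by the graph constructor."""
    if _is_matrix_market(path):
        return SimilarityGraph(sp.csr_matrix(mmread(path)))
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            rows.append(parts[0])
            cols.append(parts[1])
            vals.append(float(parts[2]))
    index = sorted(set(rows) | set(cols))
    pos = {k: i for i, k in enumerate(index)}
    n = len(index)
    S = sp.csr_matrix(
        (vals, ([pos[r] for r in rows], [pos[c] for c in cols])), shape=(n, n)
    )
    return SimilarityGraph(S, index=index)


def write_interaction_matrix(im: InteractionMatrix, prefix: str) -> None:
    """Serialize R as ``<prefix>.mtx`` plus ``<prefix>.chems`` /
    ``<prefix>.prots`` index files (one key per line)."""
    mmwrite(f"{prefix}.mtx", im.matrix.tocoo())
    for suffix, keys in ((".chems", im.chem_index), (".prots", im.prot_index)):
        with open(prefix + suffix, "w") as fh:
            fh.write("\n".join(keys) + ("\n" if keys else ""))


def read_interaction_matrix(prefix: str) -> InteractionMatrix:
    mat = sp.csr_matrix(mmread(f"{prefix}.mtx"))
    with open(f"{prefix}.chems") as fh:
        chems = [line.rstrip("\n") for line in fh if line.strip()]
    with open(f"{prefix}.prots") as fh:
        prots = [line.rstrip("\n") for line in fh if line.strip()]
    return InteractionMatrix(chems, prots, mat)


def write_imputation_network(q: ImputationNetwork, path: str) -> None:
    """Q as TSV triples with a confidence-weight column."""
    with open(path, "w") as fh:
        fh.write("chemical_key\tprotein_key\tvalue\tweight\n")
        for (chem, prot), (value, weight) in sorted(q.items()):
            fh.write(f"{chem}\t{prot}\t{value:.6g}\t{weight:.6g}\n")


def read_imputation_network(path: str) -> ImputationNetwork:
    df = pd.read_csv(path, sep="\t")
    return ImputationNetwork(
        {
            (str(r["chemical_key"]), str(r["protein_key"])): (float(r["value"]), float(r["weight"]))
            for _, r in df.iterrows()
        }
    )


def read_dose_response(
    path: str, time_zero_count: Optional[float] = None
) -> DoseResponseCurve:
    """Curve from a table with columns dose_uM, response (replicates at the
    same dose are averaged)."""
    df = pd.read_csv(path, sep=_sep(path))
    grouped = df.groupby("dose_uM")["response"].mean().sort_index()
    return DoseResponseCurve(
        doses=tuple(grouped.index), responses=tuple(grouped), time_zero_count=time_zero_count
    )


def read_expression(path: str) -> pd.DataFrame:
    """Genes x cell-lines log2 expression table (first column = gene ids)."""
    return pd.read_csv(path, sep=_sep(path), index_col=0)


def read_activity_areas(path: str) -> dict[str, float]:
    df = pd.read_csv(path, sep=_sep(path))
    cell_col, aa_col = df.columns[:2]
    return {str(r[cell_col]): float(r[aa_col]) for _, r in df.iterrows()}


def read_gmt(path: str) -> dict[str, set[str]]:
    """Gene sets in GMT format: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise ValueError(f"{path}:{lineno}: GMT lines need name, description, genes")
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_report(results: Union[pd.DataFrame, dict], path: str, format: str = "tsv") -> None:
    """Write a stats table or mapping as TSV or JSON with deterministic
    column order; floats carry 6 significant digits."""
    if format not in ("tsv", "json"):
        raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")
    if format == "json":
        if isinstance(results, pd.DataFrame):
            payload = json.loads(results.to_json(orient="index"))
        else:
            payload = results
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
        return
    if isinstance(results, dict):
        results = pd.DataFrame([results])
    results.to_csv(path, sep="\t", float_format="%.6g")


def write_factor_model(model: FactorModel, prefix: str) -> None:
    """Factors as two dense TSV tables plus a JSON metadata header."""
    meta = {
        "rank": model.rank,
        "alpha": model.alpha,
        "beta": model.beta,
        "gamma": model.gamma,
        "weights": [model.weights.w_obs, model.weights.w_imp, model.weights.w_zero],
        "n_iter": model.n_iter,
        "converged": model.converged,
        "seed": model.seed,
        "final_objective": model.history[-1] if model.history else None,
    }
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")
    np.savetxt(f"{prefix}.U.tsv", model.U, delimiter="\t", fmt="%.8g")
    np.savetxt(f"{prefix}.V.tsv", model.V, delimiter="\t", fmt="%.8g")
    for suffix, keys in ((".chems", model.chem_index), (".prots", model.prot_index)):
        if keys:
            with open(prefix + suffix, "w") as fh:
                fh.write("\n".join(keys) + "\n")
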