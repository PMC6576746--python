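"""Fingerprint-based chemical-chemical similarity.

The pipeline normally consumes a precomputed chemical similarity matrix;
this helper builds one from SMILES with Morgan (ECFP-like) fingerprints and
Tanimoto similarity, for small compound sets where no precomputed matrix is
available.  Requires rdkit (optional dependency)."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["tanimoto_similarity_matrix"]


def tanimoto_similarity_matrix(
    smiles: Sequence[str], radius: int = 2, n_bits: int = 2048, min_similarity: float = 0.0
) -> sp.csr_matrix:
    """Symmetric Tanimoto similarity matrix (zero diagonal) from SMILES."""
    try:
        from rdkit import Chem
        from rdkit.Chem import AllChem
        from rdkit.DataStructs import TanimotoSimilarity
    except ImportError as exc:  # pragma: no cover
        raise ImportError("tanimoto_similarity_matrix requires rdkit") from exc

    fps = []
    gen = AllChem.GetMorganGenerator(radius=radius, fpSize=n_bits)
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"could not parse SMILES {s!r}")
        fps.append(gen.GetFingerprint(mol))
    n = len(fps)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim = TanimotoSimilarity(fps[i], fps[j])
            if sim > min_similarity:
                S[i, j] = S[j, i] = sim
    return sp.csr_matrix(S)
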