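"""Standardization of heterogeneous bioactivity records into a one-class
chemical-protein interaction matrix.

Activity records come from chemical-genomics sources that report potency in
incompatible units: IC50 (µM), Ki (µM), pKi (unitless, -log10 molar), or
percent inhibition at a stated compound concentration.  Everything is reduced
to a binary active/inactive call with the conventional cut-offs

* IC50  <= 10 µM  -> active
* Ki    <=  5 µM  -> active (percent-inhibition records are first converted
  to an apparent Ki)
* pKi   >=  5     -> active (equivalent to Ki <= 10 µM on the molar scale)

and the active pairs are assembled into a sparse interaction matrix ``R``
(chemicals x proteins).  Only positive associations are stored: absence of an
entry means "unobserved", never "inactive" — the one-class setting the
downstream collaborative-filtering solver expects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ActivityRecord",
    "InteractionMatrix",
    "ki_from_percent_inhibition",
    "ki_from_pki",
    "is_active",
    "filter_by_confidence",
    "build_interaction_matrix",
    "MOLAR_TO_MICROMOLAR",
    "IC50_ACTIVE_UM",
    "KI_ACTIVE_UM",
    "PKI_ACTIVE",
]

MOLAR_TO_MICROMOLAR = 1e6

#: activity cut-offs, µM for the concentration-like measures
IC50_ACTIVE_UM = 10.0
KI_ACTIVE_UM = 5.0
PKI_ACTIVE = 5.0

_MEASURES = ("ic50", "ki", "pki", "percent_inhibition")


@dataclass(frozen=True)
class ActivityRecord:
    """A single standardized activity measurement.

    ``value`` is in µM for ``ic50``/``ki``, unitless for ``pki`` and a
    percentage in [0, 100] for ``percent_inhibition``.  ``concentration``
    (µM) is required exactly when the measure is ``percent_inhibition``.
    ``confidence`` is an optional source-assigned curation score; records
    from sources without such a score leave it ``None``.
    """

    chemical_key: str
    protein_key: str
    measure: str
    value: float
    concentration: Optional[float] = None
    source: str = ""
    confidence: Optional[int] = None

    def __post_init__(self) -> None:
        if self.measure not in _MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; expected one of {_MEASURES}")
        if self.measure != "pki" and self.value < 0:
            raise ValueError(f"{self.measure} value must be nonnegative, got {self.value}")
        if self.measure == "percent_inhibition":
            if not 0.0 <= self.value <= 100.0:
                raise ValueError(f"percent_inhibition must lie in [0, 100], got {self.value}")
            if self.concentration is None or self.concentration <= 0:
                raise ValueError("percent_inhibition records require a positive concentration (µM)")
        elif self.concentration is not None:
            raise ValueError("concentration is only meaningful for percent_inhibition records")


def ki_from_percent_inhibition(concentration: float, percent_inhibition: float) -> float:
    """Apparent Ki (µM) from percent inhibition at a single concentration.

    Ki = concentration * (100 - %inh) / %inh, the single-point Cheng-Prusoff
    style conversion used when only a fractional inhibition at one compound
    concentration was published.
    """
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    if percent_inhibition == 0:
        raise ZeroDivisionError("Ki is undefined at 0% inhibition")
    if not 0 < percent_inhibition <= 100:
        raise ValueError(f"percent_inhibition must lie in (0, 100], got {percent_inhibition}")
    return concentration * (100.0 - percent_inhibition) / percent_inhibition


def ki_from_pki(pki: float) -> float:
    """Ki in molar units from pKi: Ki = 10**(-pKi)."""
    if not np.isfinite(pki):
        raise ValueError(f"pKi must be finite, got {pki}")
    return float(10.0 ** (-pki))


def is_active(record: ActivityRecord) -> bool:
    """Binary activity call for one record under the standard thresholds.

    Percent-inhibition records are converted to an apparent Ki and judged
    with the 5 µM Ki rule.  Boundary values are active (``<=`` / ``>=`` as
    the cut-offs are stated).
    """
    if record.measure == "ic50":
        return record.value <= IC50_ACTIVE_UM
    if record.measure == "ki":
        return record.value <= KI_ACTIVE_UM
    if record.measure == "pki":
        return record.value >= PKI_ACTIVE
    if record.measure == "percent_inhibition":
        if record.value == 0:
            return False  # no inhibition at the tested concentration
        ki = ki_from_percent_inhibition(record.concentration, record.value)
        return ki <= KI_ACTIVE_UM
    raise ValueError(f"unknown measure {record.measure!r}")


def filter_by_confidence(
    records: Iterable[ActivityRecord], min_confidence: int = 9
) -> list[ActivityRecord]:
    """Drop records whose source-assigned confidence is present and below
    ``min_confidence``.  Records without a confidence score are kept."""
    return [r for r in records if r.confidence is None or r.confidence >= min_confidence]


@dataclass
class InteractionMatrix:
    """Sparse chemicals-x-proteins positive-association matrix ``R``.

    ``chem_index`` / ``prot_index`` give the row/column key order; ``matrix``
    is CSR with strictly positive stored values (1.0 in binary mode).
    """

    chem_index: list[str]
    prot_index: list[str]
    matrix: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.chem_index)) != len(self.chem_index):
            raise ValueError("duplicate chemical keys in index")
        if len(set(self.prot_index)) != len(self.prot_index):
            raise ValueError("duplicate protein keys in index")
        self.matrix = sp.csr_matrix(self.matrix)
        self.matrix.eliminate_zeros()
        if self.matrix.shape != (len(self.chem_index), len(self.prot_index)):
            raise ValueError("matrix shape does not match index lengths")
        if self.matrix.nnz and self.matrix.data.min() <= 0:
            raise ValueError("interaction matrix entries must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def n_pairs(self) -> int:
        return int(self.matrix.nnz)

    def pairs(self) -> set[tuple[str, str]]:
        coo = self.matrix.tocoo()
        return {
            (self.chem_index[i], self.prot_index[j]) for i, j in zip(coo.row, coo.col)
        }

    def __contains__(self, pair: tuple[str, str]) -> bool:
        chem, prot = pair
        if chem not in self.chem_index or prot not in self.prot_index:
            return False
        i = self.chem_index.index(chem)
        j = self.prot_index.index(prot)
        return self.matrix[i, j] != 0


def build_interaction_matrix(
    records: Sequence[ActivityRecord], valued: bool = False
) -> InteractionMatrix:
    """Assemble ``R`` from standardized records.

    A (chemical, protein) pair receives an entry iff at least one of its
    records is active (logical OR across sources — conflicting calls resolve
    to active, consistent with one-class positive-association semantics).
    In ``valued`` mode entries keep the maximum value observed for the pair
    mapped into (0, 1]; by default entries are binary 1.  Index order is
    lexicographic, so construction is deterministic.
    """
    active: dict[tuple[str, str], float] = {}
    for rec in records:
        if not is_active(rec):
            continue
        key = (rec.chemical_key, rec.protein_key)
        active[key] = max(active.get(key, 0.0), 1.0)
    if not active:
        warnings.warn("no active records: interaction matrix is empty", stacklevel=2)
        return InteractionMatrix([], [], sp.csr_matrix((0, 0)))

    chem_index = sorted({c for c, _ in active})
    prot_index = sorted({p for _, p in active})
    chem_pos = {c: i for i, c in enumerate(chem_index)}
    prot_pos = {p: j for j, p in enumerate(prot_index)}
    rows = np.fromiter((chem_pos[c] for c, _ in active), dtype=np.int64, count=len(active))
    cols = np.fromiter((prot_pos[p] for _, p in active), dtype=np.int64, count=len(active))
    vals = np.fromiter(active.values(), dtype=float, count=len(active))
    mat = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(chem_index), len(prot_index))
    ).tocsr()
    return InteractionMatrix(chem_index, prot_index, mat)
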