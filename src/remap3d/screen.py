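"""Structure-based off-target screening: building the imputation matrix Q.

The screen couples two structure-derived signals for a candidate off-target
protein of a template binding site:

1. a ligand-binding-site similarity p-value between the template structure
   and a candidate structure mapped to a protein accession, and
2. a protein-ligand docking score (kcal/mol-like, more negative = stronger)
   for each drug against that candidate.

A (drug, protein) pair survives the dual-threshold filter when the site
similarity p-value is below ``p_cut`` (default 2.0e-3) and the docking score
is below ``score_cut`` (default -7.5); both comparisons are strict.  The
survivors form the sparse imputation network ``Q`` that fills unobserved
cells of the interaction matrix with putative positives carrying a
confidence weight.  A uniform-imputation mode (a single scalar, default 0.1,
applied implicitly to every unobserved cell) reproduces the plain one-class
baseline without a structure screen.

The screen that produced the packaged fixture (``load_pde3b_screen``) used
the PDE3B catalytic domain as template against a non-redundant set of human
structures, docking five clinically used PDE3 inhibitors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from .activity import InteractionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SiteSimilarityHit",
    "DockingRecord",
    "ImputationNetwork",
    "UniformImputation",
    "filter_offtarget_candidates",
    "build_imputation_matrix",
    "uniform_imputation",
    "load_pde3b_screen",
    "P_VALUE_CUT",
    "DOCKING_SCORE_CUT",
]

P_VALUE_CUT = 2.0e-3
DOCKING_SCORE_CUT = -7.5


@dataclass(frozen=True)
class SiteSimilarityHit:
    """Binding-site similarity between a template and a candidate structure."""

    template_id: str
    candidate_structure: str
    protein_key: str
    p_value: float

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")


@dataclass(frozen=True)
class DockingRecord:
    """Docking score of one chemical against one protein."""

    protein_key: str
    chemical_key: str
    score: float

    def __post_init__(self) -> None:
        if not self.score == self.score or self.score in (float("inf"), float("-inf")):
            raise ValueError(f"docking score must be finite, got {self.score}")


class ImputationNetwork:
    """Sparse map (chemical_key, protein_key) -> (imputed value, weight).

    Values and weights lie in (0, 1].  Entries never overlap the observed
    matrix ``R`` they are meant to impute.
    """

    def __init__(self, entries: Mapping[tuple[str, str], tuple[float, float]] | None = None):
        self.entries: dict[tuple[str, str], tuple[float, float]] = {}
        for pair, (value, weight) in (entries or {}).items():
            self._check(value, weight)
            self.entries[pair] = (value, weight)

    @staticmethod
    def _check(value: float, weight: float) -> None:
        if not 0 < value <= 1:
            raise ValueError(f"imputed value must lie in (0, 1], got {value}")
        if not 0 < weight <= 1:
            raise ValueError(f"confidence weight must lie in (0, 1], got {weight}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.entries

    def pairs(self) -> set[tuple[str, str]]:
        return set(self.entries)

    def items(self):
        return self.entries.items()


@dataclass(frozen=True)
class UniformImputation:
    """Implicit scalar imputation: every unobserved cell carries ``value``.

    Represented as a scalar only — never materialized as a dense matrix.
    The solver folds it into its implicit-zero algebra.
    """

    value: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.value <= 1:
            raise ValueError(f"uniform imputation value must lie in (0, 1], got {self.value}")


def uniform_imputation(value: float = 0.1) -> UniformImputation:
    """Baseline imputation mode: a fixed value in every unobserved cell."""
    return UniformImputation(value)


def filter_offtarget_candidates(
    hits: Iterable[SiteSimilarityHit],
    docks: Iterable[DockingRecord],
    p_cut: float = P_VALUE_CUT,
    score_cut: float = DOCKING_SCORE_CUT,
) -> list[tuple[str, str]]:
    """Dual-threshold filter producing putative (chemical, protein) pairs.

    When several candidate structures map to one protein accession the best
    evidence is kept per pair (minimum p-value, most negative docking
    score) before thresholding.  Both thresholds are strict ``<``.  Docking
    records for proteins without any site hit are ignored (logged).  Output
    is sorted for determinism.
    """
    best_p: dict[str, float] = {}
    for hit in hits:
        prev = best_p.get(hit.protein_key)
        if prev is None or hit.p_value < prev:
            best_p[hit.protein_key] = hit.p_value

    best_score: dict[tuple[str, str], float] = {}
    for dock in docks:
        if dock.protein_key not in best_p:
            logger.info(
                "docking record for %s/%s has no site-similarity hit; ignored",
                dock.chemical_key,
                dock.protein_key,
            )
            continue
        key = (dock.chemical_key, dock.protein_key)
        prev = best_score.get(key)
        if prev is None or dock.score < prev:
            best_score[key] = dock.score

    retained = [
        (chem, prot)
        for (chem, prot), score in best_score.items()
        if best_p[prot] < p_cut and score < score_cut
    ]
    return sorted(retained)


def build_imputation_matrix(
    pairs: Sequence[tuple[str, str]],
    imputed_value: float = 1.0,
    confidence_weight: float = 0.5,
    interactions: Optional[InteractionMatrix] = None,
) -> ImputationNetwork:
    """Build ``Q`` from filtered pairs, one entry per unique pair.

    Pairs already observed in ``interactions`` (the matrix ``R``) are
    dropped: Q only fills unobserved cells.  Duplicate pairs collapse.
    """
    ImputationNetwork._check(imputed_value, confidence_weight)
    observed = interactions.pairs() if interactions is not None else set()
    entries = {}
    for pair in pairs:
        if pair in observed:
            logger.info("pair %s/%s already observed in R; omitted from Q", *pair)
            continue
        entries[pair] = (imputed_value, confidence_weight)
    return ImputationNetwork(entries)


def _fixture(name: str):
    return resources.files("remap3d.data").joinpath(name)


def load_pde3b_screen() -> tuple[list[SiteSimilarityHit], list[DockingRecord]]:
    """Load the packaged PDE3B off-target screen fixture.

    Twenty candidate structures ranked by binding-site similarity to the
    PDE3B template (PDB 1SO2), each docked against five PDE3-inhibitor
    drugs (milrinone, anagrelide, levosimendan, amrinone, enoximone).
    """
    hits = []
    with _fixture("pde3b_site_hits.tsv").open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            hits.append(
                SiteSimilarityHit(
                    template_id=row["template_id"],
                    candidate_structure=row["candidate_structure"],
                    protein_key=row["protein_key"],
                    p_value=float(row["p_value"]),
                )
            )
    docks = []
    with _fixture("pde3b_docking.tsv").open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            docks.append(
                DockingRecord(
                    protein_key=row["protein_key"],
                    chemical_key=row["chemical_key"],
                    score=float(row["score"]),
                )
            )
    return hits, docks
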