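"""Quantified feature importance: which residues' dynamics explain the
property.

For a campaign with a handful of labeled variants, each biophysical feature's
importance is the correlation between the surrogate-predicted feature values
and the experimental labels over those variants. Features are ranked by
absolute correlation (rank 1 = most important), ranks of the features
assigned to a residue are averaged into a per-residue score, and residue
rankings from many independent campaigns are combined by a median-rank
consensus. Features without a residue assignment (PCA projection weights)
are discarded before residue averaging.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.stats import pearsonr, spearmanr

__all__ = [
    "ImportanceReport",
    "ConsensusRanking",
    "feature_importance",
    "consensus_rank",
    "subset_report",
    "color_structure",
]


@dataclasses.dataclass
class ImportanceReport:
    feature_ids: tuple[str, ...]
    residues: tuple[int | None, ...]  # per feature; None = unassignable
    correlations: np.ndarray  # signed r per feature
    ranks: np.ndarray  # permutation of 1..K, 1 = most important
    residue_ranks: dict[int, float]  # residue -> mean rank of its features
    training_mutated_residues: frozenset[int] = frozenset()

    def residue_order(self) -> list[int]:
        """Residues sorted most-important first (lowest average rank)."""
        return sorted(self.residue_ranks, key=lambda r: (self.residue_ranks[r], r))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "residue": [r if r is not None else np.nan for r in self.residues],
                "r": self.correlations,
                "rank": self.ranks,
            }
        )


@dataclasses.dataclass
class ConsensusRanking:
    residues: tuple[int, ...]
    consensus_score: np.ndarray  # median per-campaign rank per residue
    final_rank: np.ndarray  # 1..R after tie-breaking
    n_campaigns: int

    def residue_order(self) -> list[int]:
        return [r for _, r in sorted(zip(self.final_rank, self.residues))]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "residue": self.residues,
                "consensus_score": self.consensus_score,
                "final_rank": self.final_rank,
            }
        ).sort_values("final_rank")


def feature_importance(
    feature_predictions: np.ndarray,
    labels: np.ndarray,
    schema,
    method: str = "pearson",
    training_mutated_residues=frozenset(),
) -> ImportanceReport:
    """Correlate predicted features with labels and rank residues.

    ``feature_predictions`` is (n_variants, |schema|), aligned with
    ``labels``. Zero-variance predictions get r = 0 and sort last (stably).
    """
    x = np.asarray(feature_predictions, float)
    y = np.asarray(labels, float)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("predictions must be (n, K) aligned with labels")
    if len(y) < 3:
        raise ValueError("need at least 3 labeled variants")
    corr_fn = {"pearson": pearsonr, "spearman": spearmanr}[method]
    k = x.shape[1]
    r = np.zeros(k)
    for j in range(k):
        if np.std(x[:, j]) > 0 and np.std(y) > 0:
            r[j] = corr_fn(x[:, j], y).statistic
    r = np.nan_to_num(r)

    order = np.lexsort((np.arange(k), -np.abs(r)))  # |r| desc, stable
    ranks = np.empty(k, dtype=int)
    ranks[order] = np.arange(1, k + 1)

    residues = tuple(e.residue for e in schema.entries)
    by_res: dict[int, list[int]] = {}
    for rank, res in zip(ranks, residues):
        if res is not None:
            by_res.setdefault(res, []).append(rank)
    residue_ranks = {res: float(np.mean(v)) for res, v in by_res.items()}
    return ImportanceReport(
        feature_ids=schema.feature_ids,
        residues=residues,
        correlations=r,
        ranks=ranks,
        residue_ranks=residue_ranks,
        training_mutated_residues=frozenset(training_mutated_residues),
    )


def consensus_rank(reports: list[ImportanceReport]) -> ConsensusRanking:
    """Median-rank consensus across campaigns.

    The consensus score of a residue is the median of its per-campaign
    average ranks; ties in the final ordering break by mean rank, then by
    residue index.
    """
    if not reports:
        raise ValueError("need at least one report")
    common = set(reports[0].residue_ranks)
    for rep in reports[1:]:
        common &= set(rep.residue_ranks)
    if not common:
        raise ValueError("reports share no residues")
    residues = tuple(sorted(common))
    mat = np.array([[rep.residue_ranks[r] for r in residues] for rep in reports])
    med = np.median(mat, axis=0)
    mean = mat.mean(axis=0)
    order = np.lexsort((residues, mean, med))
    final = np.empty(len(residues), dtype=int)
    final[order] = np.arange(1, len(residues) + 1)
    return ConsensusRanking(
        residues=residues,
        consensus_score=med,
        final_rank=final,
        n_campaigns=len(reports),
    )


def subset_report(
    reports: list[ImportanceReport], exclude_if_mutated=frozenset()
) -> ConsensusRanking:
    """Consensus over only campaigns whose training variants never mutated
    the given residues."""
    excl = frozenset(exclude_if_mutated)
    kept = [r for r in reports if not (r.training_mutated_residues & excl)]
    if not kept:
        raise ValueError("every campaign mutated an excluded residue")
    return consensus_rank(kept)


def color_structure(
    residue_scores: dict[int, float], structure_path, out_path
) -> None:
    """Write per-residue scores into the B-factor column of a PDB copy.

    Residues absent from ``residue_scores`` get 0 (with a warning).
    """
    from Bio.PDB import PDBIO, PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", structure_path)
    unmapped = []
    for model in structure:
        for chain in model:
            for residue in chain:
                pos = residue.id[1]
                score = residue_scores.get(pos)
                if score is None:
                    unmapped.append(pos)
                    score = 0.0
                for atom in residue:
                    atom.set_bfactor(float(score))
    if unmapped:
        warnings.warn(f"no score for residues {unmapped[:5]}...; wrote 0")
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(out_path))
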