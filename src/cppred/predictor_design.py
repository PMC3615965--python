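"""The hybrid classifier and the peptide-design utilities.

The hybrid rule combines the SVM decision score with motif evidence: if
any CPP motif hits the peptide at the chosen E-threshold, the SVM score
is increased by exactly +5 — large enough that any realistically scored
peptide carrying a known CPP motif is called positive at the default
threshold of 0.  The bonus is applied at most once per peptide, however
many motifs hit.

Design utilities mirror what a peptide chemist asks of a predictor:

* every single-point mutant of a peptide (19 per position), scored and
  annotated with the 11 physicochemical properties, sortable;
* a sliding-window scan of a protein for putative membrane-crossing
  regions (stride 1, user-set window);
* a motif occurrence report over any sequence.

User-facing coordinates are 1-based inclusive; internal offsets are
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import WindowTooLongError
from .features import PHYSCHEM_NAMES, encode_peptide, physchem_features
from .motif_scan import Motif, hits_table, scan_peptide
from .peptide_core import AMINO_ACIDS, Peptide, PeptideDataset
from .svm_model import TrainedModel, decision_score

HYBRID_BONUS = 5.0


@dataclass(frozen=True)
class HybridPrediction:
    peptide_id: str
    sequence: str
    svm_score: float
    motif_hit: bool
    final_score: float
    call: str                  # "CPP" | "non-CPP"
    threshold: float


def hybrid_score(m: TrainedModel, motifs: list[Motif] | None, p: Peptide,
                 e_threshold: float = 10.0,
                 threshold: float = 0.0) -> HybridPrediction:
    """Score one peptide with the SVM and the motif bonus rule."""
    svm = decision_score(m, encode_peptide(p, m.scheme))
    hit = bool(motifs) and bool(scan_peptide(p, motifs, e_threshold))
    final = svm + (HYBRID_BONUS if hit else 0.0)
    return HybridPrediction(
        peptide_id=p.id or p.sequence, sequence=p.sequence, svm_score=svm,
        motif_hit=hit, final_score=final,
        call="CPP" if final >= threshold else "non-CPP", threshold=threshold)


def predict_batch(m: TrainedModel, d: PeptideDataset,
                  motifs: list[Motif] | None = None, threshold: float = 0.0,
                  mode: str = "svm", e_threshold: float = 10.0) -> pd.DataFrame:
    """One prediction row per peptide, dataset order preserved.

    ``mode='svm'`` ignores motifs entirely; ``mode='hybrid'`` applies
    the +5 bonus.  Per-record scoring errors are collected into an
    ``error`` column instead of aborting the batch.
    """
    if mode not in ("svm", "hybrid"):
        raise ValueError("mode must be 'svm' or 'hybrid'")
    rows = []
    for p in d:
        try:
            pred = hybrid_score(m, motifs if mode == "hybrid" else None, p,
                                e_threshold=e_threshold, threshold=threshold)
            rows.append({"peptide_id": pred.peptide_id, "sequence": p.sequence,
                         "svm_score": pred.svm_score,
                         "motif_hit": pred.motif_hit,
                         "final_score": pred.final_score, "call": pred.call,
                         "error": ""})
        except Exception as e:  # record and continue
            rows.append({"peptide_id": p.id or p.sequence,
                         "sequence": p.sequence, "svm_score": np.nan,
                         "motif_hit": False, "final_score": np.nan,
                         "call": "", "error": str(e)})
    return pd.DataFrame(rows)


def generate_point_mutants(p: Peptide) -> list[Peptide]:
    """All 19 x len(p) single-point mutants, position-major then residue-
    alphabetical; the parent itself is excluded."""
    mutants = []
    for pos in range(len(p)):
        for aa in AMINO_ACIDS:
            if aa == p.sequence[pos]:
                continue
            seq = p.sequence[:pos] + aa + p.sequence[pos + 1:]
            mutants.append(Peptide(seq, id=f"{p.id or 'parent'}_{pos + 1}{aa}",
                                   label=p.label))
    return mutants


def design_report(p: Peptide, m: TrainedModel,
                  motifs: list[Motif] | None = None, threshold: float = 0.0,
                  e_threshold: float = 10.0, mode: str = "hybrid",
                  sort_key: str = "final_score",
                  ascending: bool = False) -> pd.DataFrame:
    """Parent plus every single-point mutant, scored and annotated.

    Each row carries the mutated position (1-based; 0 for the parent),
    the substituted residue, the final score and call, and the 11
    physicochemical properties.  The table is stably sorted by
    ``sort_key`` (ties keep position-then-residue order).
    """
    entries = [(0, "", p)] + [
        (pos + 1, aa, mut)
        for mut, (pos, aa) in zip(
            generate_point_mutants(p),
            [(i, a) for i in range(len(p)) for a in AMINO_ACIDS
             if a != p.sequence[i]])
    ]
    rows = []
    for pos, sub, pep in entries:
        pred = hybrid_score(m, motifs if mode == "hybrid" else None, pep,
                            e_threshold=e_threshold, threshold=threshold)
        pc = physchem_features(pep)
        row = {"sequence": pep.sequence, "position": pos, "substitution": sub,
               "is_parent": pos == 0, "svm_score": pred.svm_score,
               "motif_hit": pred.motif_hit, "final_score": pred.final_score,
               "call": pred.call}
        row.update(dict(zip(PHYSCHEM_NAMES, pc.values)))
        rows.append(row)
    table = pd.DataFrame(rows)
    if sort_key not in table.columns:
        raise ValueError(f"unknown sort key {sort_key!r}")
    return table.sort_values(sort_key, ascending=ascending,
                             kind="mergesort").reset_index(drop=True)


def scan_protein(protein: str | Peptide, w: int, m: TrainedModel,
                 motifs: list[Motif] | None = None, threshold: float = 0.0,
                 e_threshold: float = 10.0, mode: str = "svm") -> pd.DataFrame:
    """Score every length-``w`` window of a protein, stride 1.

    Returns L - w + 1 rows with 1-based inclusive ``start``/``end``
    coordinates, window sequence, scores and call — the data behind a
    penetration-propensity profile plot.
    """
    seq = protein.sequence if isinstance(protein, Peptide) else protein.upper()
    if w < 5:
        raise ValueError("window must be >= 5")
    if w > len(seq):
        raise WindowTooLongError(
            f"window {w} exceeds protein length {len(seq)}")
    parent_id = protein.id if isinstance(protein, Peptide) else "protein"
    rows = []
    for start in range(len(seq) - w + 1):
        pep = Peptide(seq[start:start + w], id=f"{parent_id}_{start + 1}")
        pred = hybrid_score(m, motifs if mode == "hybrid" else None, pep,
                            e_threshold=e_threshold, threshold=threshold)
        rows.append({"start": start + 1, "end": start + w,
                     "sequence": pep.sequence, "svm_score": pred.svm_score,
                     "motif_hit": pred.motif_hit,
                     "final_score": pred.final_score, "call": pred.call})
    return pd.DataFrame(rows)


def motif_report(sequence: str | Peptide, motifs: list[Motif],
                 e_threshold: float = 10.0) -> pd.DataFrame:
    """Motif hits over a full peptide or protein sequence, best E first.

    Offsets are reported 1-based in the ``start`` column alongside the
    0-based ``offset``.
    """
    pep = sequence if isinstance(sequence, Peptide) else Peptide(
        sequence.upper(), id="query")
    table = hits_table(scan_peptide(pep, motifs, e_threshold))
    table.insert(3, "start", table["offset"] + 1)
    return table
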