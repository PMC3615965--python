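"""Fixed-length feature encodings for variable-length peptides.

SVM training needs a fixed-length numeric representation of each peptide.
Four encodings are provided, all over the alphabetical residue order
``A,C,D,...,Y``:

* **amino-acid composition** — 20 percent frequencies, summing to 100;
* **dipeptide composition** — 400 fractions of ordered residue pairs
  among the N-1 overlapping pairs, summing to 1;
* **binary profile** — per-position one-hot blocks of the N- and/or
  C-terminal windows (N5, C5, N10, C10, N5C5, N10C10); positions beyond
  a short peptide are all-zero blocks so the length stays ``20*W``;
* **physicochemical** — 11 global descriptors (amphipathicity,
  hydrophobicity, charge, molecular weight, length, pI, side-chain bulk,
  steric bulk, donated H-bonds, polar and non-polar residue counts).

A position-frequency matrix over terminal windows is also computed for
residue-preference analysis (the input a sequence-logo renderer needs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .errors import (
    EmptyDatasetError,
    SequenceTooShortError,
    WindowTooLongError,
)
from .peptide_core import AA_INDEX, AMINO_ACIDS, Peptide, PeptideDataset

WATER_MASS = 18.01524

DIPEPTIDES: list[str] = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]

#: scheme name -> (N-window, C-window) residue counts
BINARY_SCHEMES: dict[str, tuple[int, int]] = {
    "N5": (5, 0),
    "C5": (0, 5),
    "N10": (10, 0),
    "C10": (0, 10),
    "N5C5": (5, 5),
    "N10C10": (10, 10),
}

PHYSCHEM_NAMES = [
    "amphipathicity", "hydrophobicity", "charge", "molecular_weight",
    "length", "pI", "side_chain_bulk", "steric_bulk", "h_bond_donors",
    "polar_count", "nonpolar_count",
]


@dataclass(frozen=True)
class FeatureVector:
    """A named, ordered numeric encoding of one peptide under one scheme."""

    scheme: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")

    def __len__(self) -> int:
        return len(self.values)


def _load_scales() -> pd.DataFrame:
    with resources.files("cppred.data").joinpath("physchem_scales.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", index_col="residue")


_SCALES = _load_scales()


@dataclass(frozen=True)
class PhysChemScales:
    """Per-residue numeric scales used by :func:`physchem_features`.

    The default tables bundled with the package record AAindex-style
    provenance identifiers in the resource file header.  Charge is the
    unit charge at physiological pH (Arg=Lys=+1, Asp=Glu=-1, His=0; the
    amino and carboxy termini contribute +1 and -1 and cancel).
    """

    table: pd.DataFrame = field(default_factory=lambda: _SCALES)

    def column(self, name: str) -> dict[str, float]:
        return self.table[name].to_dict()


DEFAULT_SCALES = PhysChemScales()


def aa_composition(p: Peptide) -> FeatureVector:
    """Percent amino-acid composition: ``Comp_i = R_i / N * 100``.

    ``R_i`` is the count of residue ``i`` and ``N`` the peptide length;
    the 20 components sum to 100.
    """
    counts = np.zeros(20)
    for ch in p.sequence:
        counts[AA_INDEX[ch]] += 1
    values = counts / len(p) * 100.0
    return FeatureVector("composition", tuple(AMINO_ACIDS), values)


def terminal_composition(p: Peptide, end: Literal["N", "C"], k: int) -> FeatureVector:
    """Percent composition of the first (N) or last (C) ``k`` residues."""
    if k < 1 or k > len(p):
        raise WindowTooLongError(
            f"window {k} invalid for peptide of length {len(p)}")
    window = p.sequence[:k] if end == "N" else p.sequence[-k:]
    fv = aa_composition(Peptide(window, id=p.id))
    return FeatureVector(f"composition_{end}{k}", fv.names, fv.values)


def dipeptide_composition(p: Peptide) -> FeatureVector:
    """Fractions of the 400 ordered residue pairs among overlapping pairs.

    A peptide of length N has N-1 overlapping dipeptides; each component
    is that pair's count over N-1, so the vector sums to 1.
    """
    if len(p) < 2:
        raise SequenceTooShortError("dipeptide composition needs length >= 2")
    counts = np.zeros(400)
    s = p.sequence
    for i in range(len(s) - 1):
        counts[AA_INDEX[s[i]] * 20 + AA_INDEX[s[i + 1]]] += 1
    values = counts / (len(s) - 1)
    return FeatureVector("dipeptide", tuple(DIPEPTIDES), values)


def _window_residues(seq: str, scheme: str) -> list[str | None]:
    """Residues filling each block of the scheme; None marks an unfilled pad.

    On peptides shorter than a terminal window the N window is the whole
    sequence padded at its far end, mirrored for the C window; for joined
    schemes the two windows are extracted independently and may overlap.
    """
    n_k, c_k = BINARY_SCHEMES[scheme]
    slots: list[str | None] = []
    for i in range(n_k):
        slots.append(seq[i] if i < len(seq) else None)
    for i in range(c_k):
        j = len(seq) - c_k + i
        slots.append(seq[j] if j >= 0 else None)
    return slots


def binary_profile(p: Peptide, scheme: str) -> FeatureVector:
    """One-hot binary profile of the scheme's terminal window(s).

    Each window position contributes a 20-long one-hot block (``A`` ->
    ``1,0,...,0``); N-terminal blocks come first.  Peptides shorter than
    the window leave the missing positions as all-zero blocks, keeping
    the output length at ``20*W`` as fixed-length classifiers require.
    """
    if scheme not in BINARY_SCHEMES:
        raise ValueError(f"unknown binary scheme {scheme!r}")
    slots = _window_residues(p.sequence, scheme)
    values = np.zeros(20 * len(slots))
    names = []
    for pos, res in enumerate(slots):
        for aa in AMINO_ACIDS:
            names.append(f"pos{pos + 1}_{aa}")
        if res is not None:
            values[pos * 20 + AA_INDEX[res]] = 1.0
    return FeatureVector(scheme, tuple(names), values)


def decode_binary_profile(fv: FeatureVector) -> list[str | None]:
    """Invert :func:`binary_profile`: residue per block, None for pads."""
    out: list[str | None] = []
    for pos in range(len(fv) // 20):
        block = fv.values[pos * 20:(pos + 1) * 20]
        hot = np.flatnonzero(block == 1.0)
        out.append(AMINO_ACIDS[hot[0]] if hot.size else None)
    return out


def isoelectric_point(sequence: str) -> float:
    """Peptide pI via bisection on the Henderson-Hasselbalch net charge
    (Bjellqvist pKa set, as implemented in Biopython's ProtParam)."""
    return ProteinAnalysis(sequence).isoelectric_point()


def physchem_features(p: Peptide, scales: PhysChemScales = DEFAULT_SCALES) -> FeatureVector:
    """The 11 global physicochemical descriptors, fixed order.

    Means are per-residue averages; charge, molecular weight, H-bond
    donors and the polarity counts are totals.  Molecular weight is the
    sum of average residue masses plus one water.
    """
    t = scales.table
    seq = p.sequence
    rows = t.loc[list(seq)]
    values = np.array([
        rows["amphipathicity"].mean(),
        rows["hydrophobicity"].mean(),
        rows["charge"].sum(),
        rows["residue_mass"].sum() + WATER_MASS,
        float(len(seq)),
        isoelectric_point(seq),
        rows["side_chain_bulk"].mean(),
        rows["steric_bulk"].mean(),
        rows["h_bond_donors"].sum(),
        rows["polar"].sum(),
        (1 - rows["polar"]).sum(),
    ])
    return FeatureVector("physchem", tuple(PHYSCHEM_NAMES), values)


def position_frequency_matrix(d: PeptideDataset, end: Literal["N", "C"],
                              k: int) -> tuple[pd.DataFrame, int]:
    """Relative residue frequency at each of the k terminal positions.

    Returns a 20 x k DataFrame (rows = residues, columns = positions,
    each column summing to 1) plus the number of peptides skipped for
    being shorter than k.  The matrix is the numeric input any sequence
    logo renderer consumes.
    """
    if len(d) == 0:
        raise EmptyDatasetError("position frequencies need a non-empty dataset")
    counts = np.zeros((20, k))
    skipped = 0
    for p in d:
        if len(p) < k:
            skipped += 1
            continue
        window = p.sequence[:k] if end == "N" else p.sequence[-k:]
        for j, ch in enumerate(window):
            counts[AA_INDEX[ch], j] += 1
    if counts.sum() == 0:
        raise EmptyDatasetError(f"no peptide of length >= {k} in dataset")
    freqs = counts / counts.sum(axis=0, keepdims=True)
    cols = [f"{end}{j + 1}" for j in range(k)]
    return pd.DataFrame(freqs, index=list(AMINO_ACIDS), columns=cols), skipped


_ENCODERS = {
    "composition": aa_composition,
    "dipeptide": dipeptide_composition,
    "physchem": physchem_features,
}


def encode_peptide(p: Peptide, scheme: str) -> FeatureVector:
    """Encode one peptide under any named scheme."""
    if scheme in _ENCODERS:
        return _ENCODERS[scheme](p)
    if scheme in BINARY_SCHEMES:
        return binary_profile(p, scheme)
    raise ValueError(f"unknown encoding scheme {scheme!r}")


def encode_dataset(d: PeptideDataset, scheme: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Encode a labeled dataset as (feature matrix, label vector).

    Rows preserve dataset order; columns are the scheme's fixed component
    order; labels are 1 for positive, 0 for negative.  Per-peptide
    encoding errors are re-raised with the peptide id.
    """
    if len(d) == 0:
        raise EmptyDatasetError("cannot encode an empty dataset")
    rows, names = [], None
    for p in d:
        try:
            fv = encode_peptide(p, scheme)
        except Exception as e:
            raise type(e)(f"{p.id or p.sequence}: {e}") from e
        rows.append(fv.values)
        names = fv.names
    X = pd.DataFrame(np.vstack(rows), columns=list(names),
                     index=[p.id or f"seq{i+1}" for i, p in enumerate(d)])
    y = np.array([1 if p.label == "positive" else 0 for p in d])
    return X, y
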