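"""Motif parsing and scanning for CPP-specific sequence patterns.

Motifs are position probability matrices read from MEME minimal text
format (the format motif-discovery tools emit; discovery itself is
delegated to external tools or a user-supplied motif file).  Scanning
follows the usual log-odds scheme: each window of motif width ``w`` gets
a score in bits, ``sum_pos log2(pwm[res, pos] / background[res])``, with
probabilities floored at 1e-4 before the log.

Significance is a per-peptide E-value.  The null score distribution for
a random background window is computed exactly by dynamic-programming
convolution of the per-position score distributions, after discretizing
each position's scores to a fixed step (default 0.01 bits).  The best
window p-value is Bonferroni-scaled by the number of windows and the
number of motifs scanned:  ``E = p * windows * motifs``.  A peptide with
at least one hit at the chosen E-threshold counts as "covered".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AlphabetError,
    EmptyDatasetError,
    FormatError,
    LengthMismatchError,
)
from .peptide_core import AA_INDEX, AMINO_ACIDS, Peptide, PeptideDataset

PSEUDO_PROB = 1e-4        # floor for PWM and background entries before log
DEFAULT_STEP = 0.01       # score discretization, bits

#: Table-5-style ladder of E-value thresholds, most permissive first.
E_VALUE_LADDER = (10.0, 1.0, 0.1, 0.01, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7)


class Motif:
    """A position probability matrix with a background model.

    Parameters
    ----------
    id : str
        Motif name from the MOTIF line.
    pwm : (20, w) array
        Per-position residue probabilities, rows in alphabetical
        one-letter order; each column sums to 1.
    background : (20,) array
        Background residue frequencies, summing to 1.
    source_evalue : float
        Discovery E-value carried as metadata only.
    """

    def __init__(self, id: str, pwm: np.ndarray,
                 background: np.ndarray | None = None,
                 source_evalue: float = float("nan"),
                 step: float = DEFAULT_STEP):
        pwm = np.asarray(pwm, dtype=float)
        if pwm.ndim != 2 or pwm.shape[0] != 20 or pwm.shape[1] < 2:
            raise ValueError("pwm must be 20 x w with w >= 2")
        if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-3):
            raise ValueError("pwm columns must each sum to 1")
        if background is None:
            background = np.full(20, 1 / 20)
        background = np.asarray(background, dtype=float)
        self.id = id
        self.pwm = pwm
        self.background = background
        self.source_evalue = source_evalue
        self.step = step
        # per-position log-odds in bits, floored to avoid -inf
        self.logodds = np.log2(np.maximum(pwm, PSEUDO_PROB)
                               / np.maximum(background[:, None], PSEUDO_PROB))
        # integer score bins per (residue, position)
        self._bins = np.rint(self.logodds / step).astype(np.int64)
        self._dist: tuple[int, np.ndarray] | None = None

    @property
    def width(self) -> int:
        return self.pwm.shape[1]

    def __repr__(self):
        return f"Motif({self.id!r}, w={self.width})"

    # -- exact null score distribution ---------------------------------

    def _score_distribution(self) -> tuple[int, np.ndarray]:
        """(offset, probs): P(binned score = offset + i) under background.

        Built by convolving per-position distributions over the 20
        residues weighted by background frequency; exact for the
        discretized scores up to float summation.
        """
        if self._dist is not None:
            return self._dist
        bg = self.background / self.background.sum()
        lo = int(self._bins.min(axis=0).sum())
        hi = int(self._bins.max(axis=0).sum())
        probs = np.zeros(hi - lo + 1)
        # running support [cur_lo, cur_lo + len(cur) - 1]
        cur = np.array([1.0])
        cur_lo = 0
        for pos in range(self.width):
            col = self._bins[:, pos]
            new_lo = cur_lo + int(col.min())
            new = np.zeros(len(cur) + int(col.max()) - int(col.min()))
            for r in range(20):
                shift = int(col[r]) - int(col.min())
                new[shift:shift + len(cur)] += bg[r] * cur
            cur, cur_lo = new, new_lo
        probs[cur_lo - lo:cur_lo - lo + len(cur)] = cur
        self._dist = (lo, probs)
        return self._dist


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in one peptide."""

    motif_id: str
    peptide_id: str
    offset: int          # 0-based window start
    score: float         # log-odds, bits
    pvalue: float
    evalue: float


@dataclass(frozen=True)
class MotifEvalSummary:
    """Motif-only classifier performance at one E-threshold."""

    e_threshold: float
    pcp: float           # precision among covered peptides; NaN if none
    coverage: float      # percent of peptides with >= 1 hit
    covered: int
    total: int


def parse_meme_motifs(path: str | Path) -> list[Motif]:
    """Parse all motifs from a MEME minimal format file.

    The file must declare a protein alphabet; the letter-probability
    matrix rows are remapped to alphabetical residue order.  Background
    letter frequencies are taken from the file or default to uniform.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    alphabet: str | None = None
    background: np.ndarray | None = None
    motifs: list[Motif] = []
    i = 0
    n = len(lines)
    if not any(l.strip().startswith("MEME version") for l in lines[:10]):
        raise FormatError(f"{path}: missing 'MEME version' header")
    while i < n:
        line = lines[i].strip()
        if line.startswith("ALPHABET="):
            alphabet = line.split("=", 1)[1].strip()
            if set(alphabet) <= set("ACGTU"):
                raise AlphabetError(
                    f"{path}:{i + 1}: nucleotide alphabet; protein motifs required")
            if sorted(alphabet) != sorted(AMINO_ACIDS):
                raise AlphabetError(
                    f"{path}:{i + 1}: alphabet is not the 20 amino acids")
            i += 1
        elif line.startswith("Background letter frequencies"):
            i += 1
            tokens: list[str] = []
            while i < n and lines[i].strip() and not lines[i].startswith("MOTIF"):
                tokens += lines[i].split()
                i += 1
            try:
                pairs = {tokens[k]: float(tokens[k + 1])
                         for k in range(0, len(tokens), 2)}
            except (ValueError, IndexError) as e:
                raise FormatError(f"{path}:{i}: bad background line: {e}") from e
            background = np.array([pairs.get(aa, 0.0) for aa in AMINO_ACIDS])
            if not np.isclose(background.sum(), 1.0, atol=1e-2):
                raise FormatError(f"{path}:{i}: background does not sum to 1")
        elif line.startswith("MOTIF"):
            name = line.split()[1] if len(line.split()) > 1 else f"motif{len(motifs)+1}"
            i += 1
            while i < n and not lines[i].strip().startswith("letter-probability"):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}:{i}: MOTIF {name} has no matrix")
                i += 1
            if i >= n:
                raise FormatError(f"{path}: MOTIF {name} has no matrix")
            header = lines[i].strip()
            fields = dict(zip(header.split()[1::2], header.split()[2::2]))
            try:
                w = int(fields.get("w=", fields.get("w", "0")) or 0)
            except ValueError:
                w = 0
            # tolerant parse of "alength= 20 w= 7 ... E= 1e-5"
            toks = header.replace("=", "= ").split()
            for k, t in enumerate(toks):
                if t == "w=" and k + 1 < len(toks):
                    w = int(toks[k + 1])
            evalue = float("nan")
            for k, t in enumerate(toks):
                if t == "E=" and k + 1 < len(toks):
                    evalue = float(toks[k + 1])
            if w < 2:
                raise FormatError(f"{path}:{i + 1}: motif width must be >= 2")
            i += 1
            rows = []
            while i < n and len(rows) < w:
                row_line = lines[i].strip()
                if not row_line:
                    i += 1
                    continue
                try:
                    row = [float(x) for x in row_line.split()]
                except ValueError as e:
                    raise FormatError(f"{path}:{i + 1}: bad matrix row: {e}") from e
                if len(row) != len(alphabet or AMINO_ACIDS):
                    raise FormatError(
                        f"{path}:{i + 1}: expected {len(alphabet or AMINO_ACIDS)}"
                        f" probabilities, got {len(row)}")
                if abs(sum(row) - 1.0) > 1e-3:
                    raise FormatError(
                        f"{path}:{i + 1}: matrix row sums to {sum(row):.4f}, not 1")
                rows.append(row)
                i += 1
            if len(rows) < w:
                raise FormatError(f"{path}: MOTIF {name}: matrix truncated")
            order = alphabet or AMINO_ACIDS
            pwm = np.zeros((20, w))
            for pos, row in enumerate(rows):
                for letter, prob in zip(order, row):
                    pwm[AA_INDEX[letter], pos] = prob
            motifs.append(Motif(name, pwm, background, source_evalue=evalue))
        else:
            i += 1
    if not motifs:
        raise FormatError(f"{path}: no MOTIF blocks found")
    return motifs


def default_motifs() -> list[Motif]:
    """The bundled synthetic CPP-like motif set (poly-Arg, spaced R-x-R,
    amphipathic LK repeat)."""
    from importlib import resources
    with resources.as_file(resources.files("cppred.data")
                           .joinpath("cpp_motifs_synthetic.meme")) as p:
        return parse_meme_motifs(p)


def score_window(m: Motif, window: str) -> float:
    """Log-odds score of a single window of exactly motif width, in bits."""
    if len(window) != m.width:
        raise LengthMismatchError(
            f"window length {len(window)} != motif width {m.width}")
    return float(sum(m.logodds[AA_INDEX[ch], pos]
                     for pos, ch in enumerate(window)))


def _binned_window_score(m: Motif, window: str) -> int:
    return int(sum(m._bins[AA_INDEX[ch], pos] for pos, ch in enumerate(window)))


def _pvalue_from_bin(m: Motif, sbin: int) -> float:
    lo, probs = m._score_distribution()
    idx = sbin - lo
    if idx <= 0:
        return 1.0
    if idx >= len(probs):
        return 0.0
    # sum the upper tail from the top for numerical stability
    return float(min(1.0, probs[idx:][::-1].cumsum()[-1]))


def score_pvalue(m: Motif, s: float) -> float:
    """P(window score >= s) for a background-random window.

    Exact for the discretized score model: the query is binned with the
    same step as the per-position scores and the tail mass of the
    convolved distribution is returned.
    """
    if s == float("-inf"):
        return 1.0
    return _pvalue_from_bin(m, int(np.rint(s / m.step)))


def scan_peptide(p: Peptide, motifs: list[Motif],
                 e_threshold: float = 10.0) -> list[MotifHit]:
    """Best-window hits of each motif in one peptide, best E-value first.

    For each motif the minimum window p-value is converted to a
    per-peptide E-value ``p * windows * len(motifs)``; hits with
    ``E <= e_threshold`` are returned.  Peptides shorter than a motif
    yield no hit for that motif.
    """
    hits: list[MotifHit] = []
    n_motifs = len(motifs)
    for m in motifs:
        n_windows = len(p) - m.width + 1
        if n_windows < 1:
            continue
        best_off, best_bin = 0, None
        for off in range(n_windows):
            sb = _binned_window_score(m, p.sequence[off:off + m.width])
            if best_bin is None or sb > best_bin:
                best_off, best_bin = off, sb
        pval = _pvalue_from_bin(m, best_bin)
        evalue = pval * n_windows * n_motifs
        if evalue <= e_threshold:
            hits.append(MotifHit(
                motif_id=m.id, peptide_id=p.id or p.sequence,
                offset=best_off,
                score=score_window(m, p.sequence[best_off:best_off + m.width]),
                pvalue=max(pval, np.finfo(float).tiny), evalue=evalue))
    hits.sort(key=lambda h: (h.evalue, h.motif_id))
    return hits


def has_motif_hit(p: Peptide, motifs: list[Motif], e_threshold: float) -> bool:
    return bool(scan_peptide(p, motifs, e_threshold))


def hits_table(hits: list[MotifHit]) -> pd.DataFrame:
    """Hits as a tab-separable table (peptide, motif, offset, score, p, E)."""
    return pd.DataFrame(
        [(h.peptide_id, h.motif_id, h.offset, h.score, h.pvalue, h.evalue)
         for h in hits],
        columns=["peptide_id", "motif_id", "offset", "score", "pvalue", "evalue"])


def motif_only_evaluate(d: PeptideDataset, motifs: list[Motif],
                        e_thresholds=E_VALUE_LADDER) -> list[MotifEvalSummary]:
    """Evaluate the motif-only classifier over a ladder of E-thresholds.

    A peptide with at least one hit is predicted CPP ("covered").
    Coverage is the percent of peptides covered; PCP (probability of
    correct prediction) is the fraction of covered peptides that are
    true positives — NaN when nothing is covered.  Scanning is done once
    at the loosest threshold; stricter rungs reuse the hit E-values, so
    coverage is non-increasing down the ladder by construction.
    """
    if len(d) == 0:
        raise EmptyDatasetError("cannot evaluate an empty dataset")
    loosest = max(e_thresholds)
    best_e = []
    for p in d:
        hits = scan_peptide(p, motifs, e_threshold=loosest)
        best_e.append(hits[0].evalue if hits else float("inf"))
    out = []
    for thr in sorted(e_thresholds, reverse=True):
        covered_idx = [i for i, e in enumerate(best_e) if e <= thr]
        covered = len(covered_idx)
        tp = sum(1 for i in covered_idx if d[i].label == "positive")
        pcp = tp / covered if covered else float("nan")
        out.append(MotifEvalSummary(
            e_threshold=thr, pcp=pcp, coverage=100.0 * covered / len(d),
            covered=covered, total=len(d)))
    return out
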