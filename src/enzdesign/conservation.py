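"""Alignment reading, sequence weighting, and position-specific scoring.

The conservation stage turns a multiple sequence alignment into a log-odds
profile (PSSM, bits) and enumerates the non-native residues with positive
support at each position of a target sequence.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
from Bio import AlignIO, SeqIO

from enzdesign.alphabet import AA20, AA21, GAP, encode_rows
from enzdesign.errors import FormatError, InputError, ParameterError

logger = logging.getLogger(__name__)

#: Default residue background: uniform over the 20 amino acids.
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)


@dataclass
class Alignment:
    """A normalized multiple sequence alignment.

    Rows are uppercase strings over the 21-letter alphabet (20 amino acids
    plus ``-``); all rows share the same length.
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise InputError("alignment has no rows")
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"rows have unequal lengths: {sorted(lengths)}")
        if len(self.rows[0]) < 1:
            raise InputError("alignment has zero columns")
        allowed = set(AA21)
        for rid, row in zip(self.ids, self.rows):
            bad = set(row) - allowed
            if bad:
                raise FormatError(f"row {rid!r} has characters outside alphabet: {sorted(bad)}")

    @property
    def N(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0])

    def encoded(self, alphabet: str = AA21) -> np.ndarray:
        """Integer-encoded (N, L) matrix over ``alphabet``."""
        return encode_rows(self.rows, alphabet)


@dataclass
class SequenceWeights:
    """Per-row redundancy weights; ``neff`` is their sum."""

    weights: np.ndarray
    neff: float = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights <= 0).any() or (self.weights > 1).any():
            raise ParameterError("weights must lie in (0, 1]")
        self.neff = float(self.weights.sum())


@dataclass
class PSSM:
    """Log2-odds profile over alignment columns.

    ``scores`` is (L, 20) in bits, column order follows :data:`AA20`;
    positions are 1-based alignment columns.
    """

    scores: np.ndarray
    background: np.ndarray
    pseudocount_alpha: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.scores.shape[1] != 20:
            raise InputError("PSSM must have 20 residue columns")
        if not np.isclose(self.background.sum(), 1.0):
            raise ParameterError("background must sum to 1")
        if not np.isfinite(self.scores).all():
            raise ParameterError("PSSM scores must be finite")

    @property
    def L(self) -> int:
        return int(self.scores.shape[0])


class SubstitutionRecord(NamedTuple):
    """A positively-scored non-native residue at a target position (1-based)."""

    position: int
    from_residue: str
    to_residue: str
    score: float


def _normalize_row(row: str) -> str:
    """Uppercase and map non-alphabet characters (X, B, Z, '.', '*', …) to gap."""
    out = []
    for ch in row.upper():
        out.append(ch if ch in AA21 else GAP)
    return "".join(out)


def _read_a3m(path: str) -> tuple[list[str], list[str]]:
    ids, rows = [], []
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq)
        # lowercase letters are insertions relative to the master; '.' likewise
        seq = "".join(ch for ch in seq if not ch.islower() and ch != ".")
        ids.append(rec.id)
        rows.append(seq)
    return ids, rows


def read_alignment(path: str, fmt: str | None = None) -> Alignment:
    """Read an alignment in FASTA, A3M, or Stockholm format.

    ``fmt`` is one of ``"fasta"``, ``"a3m"``, ``"stockholm"``; when omitted it
    is guessed from the file extension (``.sto``/``.stk`` → Stockholm,
    ``.a3m`` → A3M, otherwise FASTA).
    """
    if not os.path.exists(path):
        raise InputError(f"alignment file not found: {path}")
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {".sto": "stockholm", ".stk": "stockholm", ".a3m": "a3m"}.get(ext, "fasta")
    fmt = fmt.lower()
    if fmt == "a3m":
        ids, rows = _read_a3m(path)
    elif fmt in ("fasta", "stockholm"):
        try:
            msa = AlignIO.read(path, fmt)
        except ValueError as exc:
            # Bio.AlignIO raises ValueError both for empty files and for
            # ragged rows; distinguish to honour the error contract.
            try:
                recs = list(SeqIO.parse(path, fmt if fmt == "fasta" else "stockholm"))
            except Exception:
                recs = []
            if not recs:
                raise InputError(f"empty or unreadable alignment: {path}") from exc
            raise FormatError(f"rows have unequal lengths in {path}") from exc
        ids = [rec.id for rec in msa]
        rows = [str(rec.seq) for rec in msa]
    else:
        raise ParameterError(f"unknown alignment format: {fmt}")
    if not rows:
        raise InputError(f"empty alignment: {path}")
    rows = [_normalize_row(r) for r in rows]
    return Alignment(ids=ids, rows=rows)


def write_alignment_fasta(aln: Alignment, path: str) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")


def compute_weights(aln: Alignment, identity_threshold: float = 0.8) -> SequenceWeights:
    """Inverse-neighborhood redundancy weights.

    The weight of a row is 1 over the number of rows (itself included) whose
    fractional identity to it is at least ``identity_threshold``.  Identity
    between two rows is the fraction of matching residues over the columns
    where both rows are non-gap (0 when no such column exists).
    """
    if not 0 < identity_threshold <= 1:
        raise ParameterError("identity_threshold must be in (0, 1]")
    enc = aln.encoded()
    gap_idx = AA21.index(GAP)
    nongap = enc != gap_idx
    N = aln.N
    counts = np.zeros(N, dtype=np.int64)
    for s in range(N):
        both = nongap & nongap[s]
        denom = both.sum(axis=1)
        eq = ((enc == enc[s]) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            ident = np.where(denom > 0, eq / np.maximum(denom, 1), 0.0)
        counts[s] = int((ident >= identity_threshold).sum())
    return SequenceWeights(weights=1.0 / counts)


def compute_pssm(
    aln: Alignment,
    w: SequenceWeights | None = None,
    alpha: float = 1.0,
    background: Iterable[float] | None = None,
) -> PSSM:
    """Weighted log2-odds profile with background-mixing pseudocounts.

    For column i and residue a::

        p_i(a) = (weighted count of a + alpha * bg(a)) / (weighted non-gap + alpha)
        score(i, a) = log2(p_i(a) / bg(a))

    Gaps are excluded from the counts; an all-gap column scores 0 everywhere
    (with a logged warning).
    """
    if alpha <= 0:
        raise ParameterError("alpha must be > 0")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(list(background), dtype=float)
    if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
        raise ParameterError("background must be 20 positive probabilities summing to 1")
    if w is None:
        w = compute_weights(aln)
    weights = np.asarray(w.weights, dtype=float)
    if weights.shape != (aln.N,):
        raise InputError("weights do not match alignment depth")

    enc = aln.encoded()
    gap_idx = AA21.index(GAP)
    counts = np.zeros((aln.L, 20))
    for a in range(20):
        counts[:, a] = (weights[:, None] * (enc == a)).sum(axis=0)
    totals = counts.sum(axis=1)

    scores = np.zeros((aln.L, 20))
    all_gap = totals == 0
    if all_gap.any():
        cols = [int(i) + 1 for i in np.nonzero(all_gap)[0]]
        logger.warning("all-gap columns scored 0 by convention: %s", cols)
    ok = ~all_gap
    p = (counts[ok] + alpha * bg) / (totals[ok, None] + alpha)
    scores[ok] = np.log2(p / bg)
    del gap_idx  # gap state never counted: indices 0..19 only
    return PSSM(scores=scores, background=bg, pseudocount_alpha=float(alpha))


def positive_substitutions(pssm: PSSM, target: str) -> list[SubstitutionRecord]:
    """All non-native residues with positive PSSM score against ``target``.

    Sorted by descending score; ties broken by (position, residue).
    """
    if len(target) != pssm.L:
        raise InputError(f"target length {len(target)} != PSSM length {pssm.L}")
    bad = set(target) - set(AA20)
    if bad:
        raise InputError(f"target residues outside 20-letter alphabet: {sorted(bad)}")
    records = []
    for i, native in enumerate(target):
        for a, res in enumerate(AA20):
            score = float(pssm.scores[i, a])
            if res != native and score > 0:
                records.append(SubstitutionRecord(i + 1, native, res, score))
    records.sort(key=lambda r: (-r.score, r.position, r.to_residue))
    return records


def write_pssm_tsv(pssm: PSSM, target: str, path: str) -> None:
    """TSV: position, native residue, then the 20 per-residue scores."""
    if len(target) != pssm.L:
        raise InputError("target length does not match PSSM")
    with open(path, "w") as fh:
        fh.write("position\tnative\t" + "\t".join(AA20) + "\n")
        for i in range(pssm.L):
            vals = "\t".join(f"{v:.6f}" for v in pssm.scores[i])
            fh.write(f"{i + 1}\t{target[i]}\t{vals}\n")
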