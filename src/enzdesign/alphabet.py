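"""Amino-acid alphabets and integer encodings."""

from __future__ import annotations

import numpy as np

#: Canonical 20-letter amino-acid alphabet, alphabetical by one-letter code.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Gap character used after normalization.
GAP = "-"

#: 21-state alphabet with the gap as the last state.
AA21 = AA20 + GAP

_AA20_SET = frozenset(AA20)


def encoder(alphabet: str) -> np.ndarray:
    """Return a 128-entry lookup table mapping ASCII codes to state indices.

    Characters outside ``alphabet`` map to -1.
    """
    table = np.full(128, -1, dtype=np.int64)
    for i, ch in enumerate(alphabet):
        table[ord(ch)] = i
    return table


def encode_rows(rows: list[str], alphabet: str = AA21) -> np.ndarray:
    """Encode aligned rows as an (N, L) integer matrix over ``alphabet``.

    Raises ``ValueError`` if any character is missing from the alphabet.
    """
    table = encoder(alphabet)
    buf = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    enc = table[buf].reshape(len(rows), -1)
    if (enc < 0).any():
        bad = {rows[i][j] for i, j in zip(*np.nonzero(enc < 0))}
        raise ValueError(f"characters not in alphabet {alphabet!r}: {sorted(bad)}")
    return enc


def is_standard_aa(ch: str) -> bool:
    return ch in _AA20_SET
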