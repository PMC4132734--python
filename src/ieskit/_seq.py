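"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = ("A", "C", "G", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def as_prob_vector(table: dict[str, float]) -> np.ndarray:
    """Turn a base->probability mapping into a vector over A,C,G,T.

    Raises ValueError if probabilities are negative or do not sum to 1.
    """
    p = np.array([float(table.get(b, 0.0)) for b in BASES], dtype=float)
    if (p < 0).any():
        raise ValueError(f"negative base probability in {table!r}")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"base probabilities must sum to 1, got {p.sum()!r}")
    return p


def random_seq(rng: np.random.Generator, n: int, table: dict[str, float]) -> str:
    """Draw an i.i.d. sequence of length ``n`` from a base-probability table."""
    if n <= 0:
        return ""
    p = as_prob_vector(table)
    idx = rng.choice(4, size=n, p=p)
    return "".join(BASES[i] for i in idx)
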