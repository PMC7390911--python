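"""Small shared helpers: rounding and RNG derivation."""

from __future__ import annotations

import zlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (half-up), as printed percentages are.

    Python's built-in ``round`` uses banker's rounding, which would turn
    73.5 into 74 but 34.5 into 34; reported percentages always round half
    up instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    v = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return v if ndigits > 0 else int(v) if float(v).is_integer() else v


def pct_half_up(numerator: float, denominator: float, ndigits: int = 0) -> float:
    if denominator == 0:
        raise ValueError("percentage undefined for zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def derive_rng(seed: int, *tags: object) -> np.random.Generator:
    """Deterministically derive an independent RNG stream for a pipeline stage.

    Tags (stage names, replicate ids, ...) are folded into the seed sequence
    so each stage gets its own stream while staying reproducible from one
    global seed.
    """
    tag_ints = [zlib.crc32(str(t).encode()) % (2**31) for t in tags]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *tag_ints]))
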