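"""Shared helpers: seeded substreams and rounding conventions."""
from __future__ import annotations

import zlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, reproducible random substream.

    All randomness in the package flows from one root seed; each table or
    stage draws from its own substream so that changing one recipe does not
    perturb the others.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention of reported percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator, half-up rounded to ``decimals``."""
    if denominator == 0:
        raise ValueError("percentage undefined for a zero denominator")

    def _dec(x):
        return Decimal(int(x)) if float(x).is_integer() else Decimal(repr(float(x)))

    exact = _dec(numerator) * 100 / _dec(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(q, rounding=ROUND_HALF_UP))
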