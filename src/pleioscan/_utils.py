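"""Internal helpers: seed derivation, p/z conversions."""

from __future__ import annotations

import hashlib

import numpy as np
from scipy import stats

# smallest positive normal double; p-values are floored here to stay in (0, 1]
TINY_P = np.finfo(np.float64).tiny


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from a master seed and a stage name.

    Stable across processes and Python versions (unlike ``hash``), so the same
    run configuration always reproduces the same per-stage streams.
    """
    digest = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def z_to_p(z: np.ndarray) -> np.ndarray:
    """Two-sided normal p-value for signed z-scores, floored into (0, 1]."""
    p = 2.0 * stats.norm.sf(np.abs(np.asarray(z, dtype=float)))
    return np.clip(p, TINY_P, 1.0)


def neglog10(p: np.ndarray, cap: float | None = None) -> np.ndarray:
    x = -np.log10(np.clip(np.asarray(p, dtype=float), TINY_P, 1.0))
    if cap is not None:
        x = np.clip(x, 0.0, cap)
    return x
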