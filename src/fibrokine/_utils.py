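"""Shared helpers: seeded RNG fan-out, BH adjustment, small numerics."""

from __future__ import annotations

import hashlib
import json
from typing import Iterable

import numpy as np


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed.

    Uses :class:`numpy.random.SeedSequence` spawning so stages of a pipeline
    are independently reproducible from a single recorded seed.
    """
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


def rng_from(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs are excluded from the family."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.sum() == 0:
        return out
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def bonferroni(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = np.isfinite(p).sum()
    return np.minimum(p * m, 1.0)


def mad_sd(x: np.ndarray) -> float:
    """Robust SD estimate via median absolute deviation (normal-consistent)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def check_unique(items: Iterable, what: str) -> None:
    items = list(items)
    if len(set(items)) != len(items):
        seen, dups = set(), set()
        for it in items:
            if it in seen:
                dups.add(it)
            seen.add(it)
        raise ValueError(f"duplicate {what}: {sorted(dups)[:5]}")
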