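"""Spatial colocalization of signatures and topics, and neighbourhood contrasts.

Signature scores and topic proportions live on the same capture spots, so
colocalization is simply their Pearson correlation across spots.  The
neighbourhood contrast formalises the "dampening halo" analysis: spots with
the highest anchor-signature score (e.g. the DLL4 response), their immediate
hexagonal neighbours, and all remaining spots are compared on a response
signature with an ordered-alternative rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hexgrid import neighbor_sets, offset_to_axial


@dataclass
class SpotScores:
    """Per-spot signature scores and topic proportions with array coordinates."""

    scores: pd.DataFrame  # spots x (signatures + topics)
    coords: pd.DataFrame  # spots x (array_row, array_col)
    sample: pd.Series | None = None

    def __post_init__(self):
        if not self.scores.index.equals(self.coords.index):
            raise ValueError("scores and coordinates must share barcodes")
        if self.sample is None:
            self.sample = pd.Series("sample0", index=self.scores.index)
        for s, grp in self.coords.groupby(self.sample):
            if grp.duplicated(["array_row", "array_col"]).any():
                raise ValueError(f"duplicate spot coordinates in sample {s!r}")


def correlate_spotwise(ss: SpotScores, combine_samples: bool = True):
    """Pearson correlation of every pair of score/topic columns across spots.

    With ``combine_samples`` (the default) spots from all samples enter one
    correlation; otherwise a dict of per-sample matrices is returned.
    Zero-variance columns yield missing rows/columns with a warning.  The
    matrix is symmetric with unit diagonal on the valid block.
    """

    def one(df: pd.DataFrame) -> pd.DataFrame:
        if len(df) < 10:
            raise ValueError("need >= 10 spots for spot-wise correlation")
        sd = df.std(ddof=0)
        dead = list(sd.index[sd == 0])
        if dead:
            warnings.warn(f"zero-variance column(s) set to missing: {dead}", stacklevel=3)
        corr = df.corr()  # pandas yields NaN for constant columns
        vals = corr.to_numpy()
        vals = np.clip((vals + vals.T) / 2.0, -1.0, 1.0)
        corr = pd.DataFrame(vals, index=corr.index, columns=corr.columns)
        for c in corr.columns:
            if c not in dead:
                corr.loc[c, c] = 1.0
        return corr

    if combine_samples:
        return one(ss.scores)
    return {s: one(grp) for s, grp in ss.scores.groupby(ss.sample)}


def neighborhood_contrast(
    ss: SpotScores,
    anchor_signature: str,
    response_signature: str,
    quantile: float = 0.9,
    n_perm: int = 999,
    seed: int = 0,
    min_group: int = 5,
) -> dict:
    """Three-group neighbourhood contrast around anchor-high spots.

    Spots are partitioned into anchor-high (top ``1 - quantile`` fraction of
    the anchor score), adjacent (hexagonal neighbours of anchor-high spots
    that are not themselves anchor-high) and distal (the rest).  Reports the
    mean response score per group and a Monte-Carlo Jonckheere-Terpstra
    p-value for an ordered trend across the three groups (either direction).
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie strictly in (0, 1)")
    for col in (anchor_signature, response_signature):
        if col not in ss.scores.columns:
            raise ValueError(f"column {col!r} not in scores")
    anchor = ss.scores[anchor_signature].to_numpy(dtype=float)
    response = ss.scores[response_signature].to_numpy(dtype=float)
    n = len(anchor)

    cut = np.quantile(anchor, quantile)
    high = anchor >= cut
    q, r = offset_to_axial(
        ss.coords["array_row"].to_numpy(), ss.coords["array_col"].to_numpy()
    )
    nbrs = neighbor_sets(q, r)
    adjacent = np.zeros(n, dtype=bool)
    for i in np.where(high)[0]:
        for j in nbrs[i]:
            adjacent[j] = True
    adjacent &= ~high
    distal = ~(high | adjacent)

    groups = {"anchor_high": high, "adjacent": adjacent, "distal": distal}
    for name, mask in groups.items():
        if mask.sum() < min_group:
            raise ValueError(f"group {name!r} has {int(mask.sum())} spots (< {min_group})")

    labels = np.zeros(n, dtype=int)  # 0 = anchor_high, 1 = adjacent, 2 = distal
    labels[adjacent] = 1
    labels[distal] = 2

    def jt_stat(lab: np.ndarray) -> float:
        """Jonckheere-Terpstra statistic for increasing trend over group order."""
        stat = 0.0
        for a in range(3):
            for b in range(a + 1, 3):
                xa = response[lab == a]
                xb = response[lab == b]
                # Mann-Whitney count of pairs xb > xa (ties count half)
                order = np.argsort(np.concatenate([xa, xb]), kind="stable")
                ranks = pd.Series(np.concatenate([xa, xb])).rank().to_numpy()
                rb = ranks[len(xa) :].sum()
                stat += rb - len(xb) * (len(xb) + 1) / 2.0
                _ = order
        return stat

    obs = jt_stat(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = jt_stat(rng.permutation(labels))
    # two-sided: trend in either direction
    dev = abs(obs - null.mean())
    p = (1 + int((np.abs(null - null.mean()) >= dev - 1e-12).sum())) / (n_perm + 1)

    means = {name: float(response[mask].mean()) for name, mask in groups.items()}
    ordered = (
        means["anchor_high"] <= means["adjacent"] <= means["distal"]
        or means["anchor_high"] >= means["adjacent"] >= means["distal"]
    )
    return {
        "group_means": means,
        "group_sizes": {k: int(v.sum()) for k, v in groups.items()},
        "jt_stat": float(obs),
        "p": float(p),
        "monotone": bool(ordered),
    }
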