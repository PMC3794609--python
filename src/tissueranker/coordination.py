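"""Core coordinated-expression math and tissue ranking.

For each complex (hub H with interactors I_1..I_n) and tissue t, the
coordination score is the mean Pearson correlation between the hub's
expression profile and each interactor's profile across the samples of
that tissue:

    rho_bar(C, t) = (1/n) * sum_i PCC(e_H, e_Ii)  over tissue-t samples.

Because replicate counts differ strongly between tissues, the averaged
correlation is Fisher-transformed, z = atanh(rho_bar), and standardized.
The default ("analytic") standardization multiplies by sqrt(n_t - 3), the
reciprocal standard error of a Fisher-transformed correlation estimated
from n_t samples, so scores from small and large tissues are on one scale.
An "empirical" alternative z-scores each tissue column against the
distribution over complexes.  Tissues are finally ranked per complex by
decreasing score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionCompendium
from .network import ProteinComplex

logger = logging.getLogger(__name__)

__all__ = [
    "CoordinationMatrix",
    "TissueRanking",
    "pairwise_pcc",
    "complex_coordination",
    "coordination_matrix",
    "fisher_transform",
    "standardize",
    "rank_tissues",
]

#: |r| is clamped to this before atanh so perfect correlations stay finite.
FISHER_CLAMP = 1.0 - 1e-6


@dataclass
class CoordinationMatrix:
    """Complexes x tissues coordination scores in three layers.

    ``raw`` holds mean hub-interactor PCCs in [-1, 1] (NaN = missing),
    ``fisher`` the entrywise atanh of ``raw``, and ``z`` the standardized
    scores.  ``n_interactors_used`` counts the interactors contributing to
    each cell and ``n_samples`` the replicates per tissue.
    """

    raw: pd.DataFrame
    fisher: pd.DataFrame
    z: pd.DataFrame
    n_samples: dict[str, int]
    n_interactors_used: pd.DataFrame
    standardization: str = "analytic"

    @property
    def complexes(self) -> list[str]:
        return list(self.raw.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.raw.columns)

    def write(self, outdir: str | Path, prefix: str = "coordination") -> None:
        """Serialize as three TSV matrices plus a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for layer in ("raw", "fisher", "z"):
            getattr(self, layer).to_csv(outdir / f"{prefix}.{layer}.tsv", sep="\t")
        sidecar = {
            "n_samples": self.n_samples,
            "standardization": self.standardization,
            "n_complexes": len(self.complexes),
            "n_tissues": len(self.tissues),
        }
        (outdir / f"{prefix}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


@dataclass(frozen=True)
class TissueRanking:
    """Tissues of one complex ordered by non-increasing score.

    Missing scores (NaN) sort after all finite scores; ties are broken
    lexicographically by tissue label, making the order deterministic.
    """

    complex_id: str
    entries: tuple[tuple[str, float], ...]

    @property
    def tissues(self) -> list[str]:
        return [t for t, _ in self.entries]

    def rank_of(self, tissue: str) -> int:
        """1-based rank of a tissue."""
        for i, (t, _) in enumerate(self.entries, start=1):
            if t == tissue:
                return i
        raise KeyError(tissue)

    def top(self, k: int) -> list[str]:
        return self.tissues[:k]

    def reversed(self) -> "TissueRanking":
        return TissueRanking(self.complex_id, tuple(reversed(self.entries)))


def pairwise_pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Returns NaN (missing) when either vector has zero variance: a constant
    profile carries no co-expression evidence.  Requires length >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def complex_coordination(
    cx: ProteinComplex,
    c: ExpressionCompendium,
    tissue: str,
    fisher_before_average: bool = False,
) -> tuple[float, int]:
    """Mean hub-interactor PCC for one complex in one tissue.

    Interactors absent from the expression matrix, or whose pair PCC is
    undefined (zero variance), are dropped from the mean; ``n_used``
    reports how many contributed.  A hub absent from the matrix yields
    ``(nan, 0)``: the hub profile anchors every term of the average.

    With ``fisher_before_average`` the atanh of each pair PCC is averaged
    instead of the raw PCCs (the mean is then on the Fisher scale).
    """
    if tissue not in c.tissues:
        raise ValueError(f"unknown tissue {tissue!r}")
    block = c.tissue_values(tissue)
    if block.shape[1] < 3:
        raise ValueError(f"tissue {tissue!r} has fewer than 3 samples")
    if cx.hub not in block.index:
        return float("nan"), 0
    hub = block.loc[cx.hub].to_numpy()
    vals = []
    for it in cx.interactors:
        if it not in block.index:
            continue
        r = pairwise_pcc(hub, block.loc[it].to_numpy())
        if np.isnan(r):
            continue
        vals.append(fisher_transform(r) if fisher_before_average else r)
    if not vals:
        return float("nan"), 0
    return float(np.mean(vals)), len(vals)


def coordination_matrix(
    cxs: list[ProteinComplex],
    c: ExpressionCompendium,
    mode: str = "analytic",
    fisher_before_average: bool = False,
) -> CoordinationMatrix:
    """Compute the complexes x tissues coordination matrix (all layers).

    Complexes whose raw row is entirely missing (hub absent, or no usable
    interactor anywhere) are dropped with a logged count.
    """
    if not cxs:
        raise ValueError("need at least one complex")
    tissues = c.tissues
    if len(tissues) < 2:
        raise ValueError("need at least two tissues")
    hubs = [cx.hub for cx in cxs]
    raw = pd.DataFrame(np.nan, index=hubs, columns=tissues, dtype=float)
    n_used = pd.DataFrame(0, index=hubs, columns=tissues, dtype=int)
    for cx in cxs:
        for t in tissues:
            m, n = complex_coordination(cx, c, t, fisher_before_average)
            raw.loc[cx.hub, t] = m
            n_used.loc[cx.hub, t] = n
    all_missing = raw.isna().all(axis=1)
    if all_missing.any():
        logger.info("dropping %d complex(es) with no usable scores", int(all_missing.sum()))
        raw = raw[~all_missing]
        n_used = n_used[~all_missing]
    if raw.empty:
        raise ValueError("every complex row is missing")
    if fisher_before_average:
        fisher = raw.copy()  # averaging already happened on the Fisher scale
    else:
        fisher = raw.map(fisher_transform)
    n_samples = {t: c.n_samples(t) for t in tissues}
    m = CoordinationMatrix(
        raw=raw,
        fisher=fisher,
        z=pd.DataFrame(np.nan, index=raw.index, columns=raw.columns),
        n_samples=n_samples,
        n_interactors_used=n_used,
    )
    return standardize(m, mode=mode)


def fisher_transform(r: float, clamp: float = FISHER_CLAMP) -> float:
    """Fisher z-transform atanh(r) = 0.5*ln((1+r)/(1-r)), clamped.

    |r| is clamped to ``clamp`` (default 1 - 1e-6) so correlations of
    exactly +/-1 map to large finite values instead of infinity.
    """
    if np.isnan(r):
        return float("nan")
    return float(np.arctanh(np.clip(r, -clamp, clamp)))


def standardize(m: CoordinationMatrix, mode: str = "analytic") -> CoordinationMatrix:
    """Fill the z layer from the fisher layer.

    analytic (default)
        ``z[c,t] = fisher[c,t] * sqrt(n_t - 3)`` — divides by the standard
        error 1/sqrt(n_t - 3) of a Fisher-transformed correlation, so
        tissues with few replicates are deflated.  Requires n_t >= 4.
    empirical
        Per-tissue column z-score over complexes (sample sd, ddof=1).
    """
    if mode == "analytic":
        factors = {}
        for t in m.tissues:
            n = m.n_samples[t]
            if n <= 3:
                raise ValueError(f"analytic standardization needs n >= 4 in tissue {t!r}")
            factors[t] = np.sqrt(n - 3.0)
        z = m.fisher * pd.Series(factors)
    elif mode == "empirical":
        mu = m.fisher.mean(axis=0)
        sd = m.fisher.std(axis=0, ddof=1)
        zero = sd[sd == 0].index.tolist()
        if zero:
            raise ValueError(f"zero standard deviation in tissue column(s) {zero}")
        z = (m.fisher - mu) / sd
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    return replace(m, z=z, standardization=mode)


def rank_tissues(m: CoordinationMatrix, complex_id: str, layer: str = "z") -> TissueRanking:
    """Rank a complex's tissues by decreasing score in the chosen layer.

    Missing scores sort last; ties break lexicographically by label.
    """
    if layer not in {"raw", "fisher", "z"}:
        raise ValueError(f"unknown layer {layer!r}")
    if complex_id not in m.raw.index:
        raise ValueError(f"unknown complex {complex_id!r}")
    row = getattr(m, layer).loc[complex_id]
    order = sorted(
        row.items(),
        key=lambda kv: (np.isnan(kv[1]), -kv[1] if not np.isnan(kv[1]) else 0.0, kv[0]),
    )
    return TissueRanking(complex_id, tuple((t, float(s)) for t, s in order))


def write_rankings(rankings: list[TissueRanking], path: str | Path) -> None:
    """Export rankings as TSV with columns complex, rank, tissue, score."""
    rows = [
        {"complex": r.complex_id, "rank": i, "tissue": t, "score": s}
        for r in rankings
        for i, (t, s) in enumerate(r.entries, start=1)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
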