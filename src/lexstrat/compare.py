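"""Statistical comparison of distance matrices.

The Mantel test asks whether two distance matrices over the same
populations covary: the statistic r is the Pearson correlation of their
strict lower triangles, and the null distribution is built by jointly
permuting the rows and columns of the second matrix. With tiny panels the
permutation space is coarse (n = 3 has only 6 permutations, so p cannot go
below ~0.17 two-sided); results should be read accordingly.

A gloss-level percentile bootstrap supplies a confidence interval for r
when the lexical matrix's underlying wordlist is available: glosses are
the natural unit of lexical sampling variation, so each replicate
resamples glosses with replacement, rebuilds the LDN matrix and recomputes
r. Geographic distance matrices are built from homeland centroid
coordinates with the haversine great-circle formula.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lexdist import ldn
from .wordlist_io import MISSING, DistanceMatrix, ValidationError, WordList

__all__ = ["MantelResult", "GeoTable", "mantel", "mantel_ci", "geo_matrix"]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


@dataclass
class MantelResult:
    """Outcome of a Mantel permutation test.

    ``r`` is the Pearson correlation of the vectorized strict lower
    triangles; ``p`` the permutation p-value at the requested tail;
    ``ci_low``/``ci_high`` the optional gloss-bootstrap percentile CI.
    """

    r: float
    p: float
    n_perm: int
    seed: int
    n: int
    tail: str = "two-sided"
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class GeoTable:
    """Homeland centroid coordinates (decimal degrees) per variety."""

    labels: list[str]
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        n = len(self.labels)
        if self.lat.shape != (n,) or self.lon.shape != (n,):
            raise ValidationError("coordinate arrays must match the label count")
        if np.any((self.lat < -90) | (self.lat > 90)):
            raise ValidationError("latitude out of [-90, 90]")
        if np.any((self.lon < -180) | (self.lon > 180)):
            raise ValidationError("longitude out of [-180, 180]")

    @classmethod
    def read_csv(cls, path: str | Path) -> "GeoTable":
        """Read a ``variety,lat,lon`` CSV (header optional)."""
        df = pd.read_csv(path, header=None, comment="#")
        try:
            float(df.iloc[0, 1])
        except (TypeError, ValueError):
            df = df.iloc[1:]
        return cls(
            labels=[str(x).strip() for x in df.iloc[:, 0]],
            lat=df.iloc[:, 1].astype(float).to_numpy(),
            lon=df.iloc[:, 2].astype(float).to_numpy(),
        )


def _harmonize(d1: DistanceMatrix, d2: DistanceMatrix) -> tuple[DistanceMatrix, DistanceMatrix]:
    s1, s2 = set(d1.labels), set(d2.labels)
    if s1 != s2:
        shared = sorted(s1 & s2)
        dropped = sorted(s1 ^ s2)
        if len(shared) < 3:
            raise ValidationError(
                f"label sets share only {len(shared)} labels: {shared}"
            )
        warnings.warn(f"label sets differ; dropping {dropped}", stacklevel=3)
        logger.info("mantel: dropped labels %s", dropped)
        return d1.submatrix(shared), d2.submatrix(shared)
    return d1, d2.submatrix(d1.labels)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    tail: str = "two-sided",
) -> MantelResult:
    """Mantel permutation test between two labeled distance matrices.

    Label sets are harmonized first (sorted intersection when they differ,
    with a warning naming the dropped labels). Permutations act by jointly
    permuting rows and columns of ``d2``; the p-value is
    ``(#{permuted |r*| >= |r|} + 1) / (n_perm + 1)`` two-sided, or with
    ``r* >= r`` for ``tail='greater'``.
    """
    if tail not in ("two-sided", "greater"):
        raise ValueError("tail must be 'two-sided' or 'greater'")
    d1, d2 = _harmonize(d1, d2)
    n = len(d1)
    if n < 3:
        raise ValidationError("mantel needs at least 3 labels")
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    v2 = d2.values[iu]
    for name, v in (("d1", v1), ("d2", v2)):
        if np.ptp(v) == 0:
            raise ValidationError(f"{name} has a constant off-diagonal (Pearson undefined)")
    c1 = v1 - v1.mean()
    r = float(np.dot(c1, v2 - v2.mean()) / (np.linalg.norm(c1) * np.linalg.norm(v2 - v2.mean())))

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    perm_v2 = d2.values[perms[:, iu[0]], perms[:, iu[1]]]  # (n_perm, m)
    pc = perm_v2 - perm_v2.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(pc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_star = (pc @ c1) / (norms * np.linalg.norm(c1))
    r_star = np.nan_to_num(r_star)  # degenerate permutations contribute r*=0
    if tail == "two-sided":
        count = int(np.sum(np.abs(r_star) >= abs(r) - 1e-12))
    else:
        count = int(np.sum(r_star >= r - 1e-12))
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r, p=p, n_perm=n_perm, seed=seed, n=n, tail=tail)


def mantel_ci(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    w: WordList,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Gloss-level percentile bootstrap CI for the Mantel r.

    ``d1`` must be the lexical matrix derived from wordlist ``w``. Each
    replicate resamples glosses with replacement, recomputes the LDN
    matrix and the correlation with ``d2``; the 2.5 and 97.5 percentiles
    of the replicate correlations are returned. Replicates in which some
    pair loses all shared glosses are discarded (and counted in the log).
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CI will be unstable", stacklevel=2)
    if set(d1.labels) != set(w.varieties):
        raise ValidationError("d1 labels do not match the wordlist varieties")
    d1h, d2h = _harmonize(d1, d2)
    labels = d1h.labels
    n, G = len(labels), len(w.glosses)
    iu = np.triu_indices(n, k=1)
    # per-gloss LDN per pair, nan where either form is missing
    per_gloss = np.full((len(iu[0]), G), np.nan)
    for p_idx, (i, j) in enumerate(zip(*iu)):
        for g_idx, g in enumerate(w.glosses):
            fa, fb = w.get(labels[i], g), w.get(labels[j], g)
            if fa is not MISSING and fb is not MISSING:
                per_gloss[p_idx, g_idx] = ldn(fa, fb)
    v2 = d2h.values[iu]
    c2 = v2 - v2.mean()
    norm2 = np.linalg.norm(c2)

    rng = np.random.default_rng(seed)
    rs: list[float] = []
    discarded = 0
    while len(rs) + discarded < n_boot:
        idx = rng.integers(0, G, size=G)
        sample = per_gloss[:, idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(sample, axis=1)
        if np.any(np.isnan(means)):
            discarded += 1
            continue
        c1 = means - means.mean()
        denom = np.linalg.norm(c1) * norm2
        if denom == 0:  # constant replicate matrix: correlation undefined
            discarded += 1
            continue
        rs.append(float(np.dot(c1, c2) / denom))
    if discarded:
        logger.info("mantel_ci: discarded %d degenerate replicates", discarded)
    if not rs:
        raise ValidationError("all bootstrap replicates were degenerate")
    lo, hi = np.percentile(rs, [2.5, 97.5])
    return float(lo), float(hi)


def geo_matrix(g: GeoTable) -> DistanceMatrix:
    """Great-circle (haversine) distance matrix in kilometers."""
    lat = np.radians(g.lat)
    lon = np.radians(g.lon)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    km = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    km = (km + km.T) / 2
    np.fill_diagonal(km, 0.0)
    return DistanceMatrix(list(g.labels), km, kind="geographic")
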