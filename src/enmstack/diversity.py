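"""Alpha and beta diversity of stacked binary ranges on a coarse grid.

Binary species ranges are aggregated onto a coarser grid system (default
~50 × 50 km cells) into a sites × species presence–absence matrix per time
slice. From it this module computes:

* alpha diversity — per-site species richness, its change between slices
  (gain / loss / stable), and paired t tests of future vs current richness;
* beta diversity — the total variance of community composition derived from
  the Jaccard dissimilarity matrix D: with A = -D∘D/2 double-centered into G,
  SStotal = trace(G), BDtotal = SStotal/(n-1), and the local contribution to
  beta diversity LCBD_i = G_ii / SStotal, a per-site index of compositional
  uniqueness summing to 1 over sites. Site-wise significance comes from a
  permutation null in which each species is shuffled independently across
  sites;
* decomposition of each pairwise Jaccard dissimilarity into replacement
  (turnover) and nestedness components (Baselga family for presence–absence
  data): with a shared species and b, c unique to either site,
  D = (b+c)/(a+b+c), Repl = 2·min(b,c)/(a+2·min(b,c)), Nes = D - Repl. Each
  (S, Repl, Nes) triplet with S = 1-D sums to 1 and can be drawn in a
  triangular (ternary) plot.

Sites predicted empty in a slice are excluded from that slice's beta-diversity
matrix (the Jaccard coefficient is undefined between two empty sites) but keep
their zero in richness maps; exclusions are recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .ensemble import BinaryRange

__all__ = [
    "GridSystem",
    "PresenceAbsenceMatrix",
    "PairCounts",
    "BetaTriplet",
    "LCBDResult",
    "aggregate_to_grid",
    "build_pa_matrix",
    "richness",
    "richness_change",
    "paired_t",
    "pair_counts",
    "jaccard_d",
    "decompose_pair",
    "decompose_matrix",
    "jaccard_matrix",
    "lcbd",
    "lcbd_permutation_test",
    "mean_triplet",
    "ternary_coords",
]


@dataclass
class GridSystem:
    """Mapping from fine raster cells to coarse analysis cells.

    The coarse grid is anchored at the origin of the fine grid's bounding
    box; a partial edge cell is kept if at least one fine cell inside the
    region mask falls in it.
    """

    fine_shape: tuple[int, int]
    fine_cell_km: float
    coarse_cell_km: float = 50.0
    region_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.coarse_cell_km < self.fine_cell_km:
            raise ValueError("coarse cells must be at least as large as fine cells")
        if self.region_mask is None:
            self.region_mask = np.ones(self.fine_shape, dtype=bool)
        self.region_mask = np.asarray(self.region_mask, dtype=bool)
        if self.region_mask.shape != tuple(self.fine_shape):
            raise ValueError("region mask shape must match the fine grid")
        rows, cols = self.fine_shape
        f = self.coarse_cell_km / self.fine_cell_km
        r_idx = np.floor(np.arange(rows) / f).astype(int)
        c_idx = np.floor(np.arange(cols) / f).astype(int)
        self._coarse_of = (r_idx[:, None] * (c_idx.max() + 1) + c_idx[None, :])
        # site ids: coarse cells containing >= 1 fine cell inside the region
        present = np.unique(self._coarse_of[self.region_mask])
        self.site_ids = [f"s{int(i):04d}" for i in present]
        self._site_index = {cid: k for k, cid in enumerate(present)}
        self._present = present
        self._ncc = c_idx.max() + 1

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def site_coords_km(self) -> pd.DataFrame:
        """Coarse-cell center coordinates (by coarse-grid indexing)."""
        rows = []
        for cid, sid in zip(self._present, self.site_ids):
            rr, cc = divmod(int(cid), self._ncc)
            rows.append({"site_id": sid,
                         "x_km": (cc + 0.5) * self.coarse_cell_km,
                         "y_km": (rr + 0.5) * self.coarse_cell_km,
                         "coarse_row": rr, "coarse_col": cc})
        return pd.DataFrame(rows)

    def aggregate(self, fine_mask: np.ndarray) -> np.ndarray:
        """Boolean per-site vector: present iff >= 1 fine cell in the site
        (restricted to the region mask) is present."""
        fine_mask = np.asarray(fine_mask, dtype=bool)
        if fine_mask.shape != tuple(self.fine_shape):
            raise ValueError("fine mask shape must match the grid system")
        eff = fine_mask & self.region_mask
        out = np.zeros(self.n_sites, dtype=bool)
        hit = np.unique(self._coarse_of[eff])
        for cid in hit:
            out[self._site_index[int(cid)]] = True
        return out


@dataclass
class PresenceAbsenceMatrix:
    """Sites × species boolean matrix for one scenario."""

    data: pd.DataFrame  # index = site ids, columns = species ids, bool
    tag: object = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(bool)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class PairCounts:
    """Shared (a) and site-unique (b, c) species counts of one site pair."""

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise ValueError("pair counts must be non-negative")


@dataclass(frozen=True)
class BetaTriplet:
    """(similarity, replacement, nestedness) shares; sums to 1."""

    s: float
    repl: float
    nes: float

    def __post_init__(self) -> None:
        total = self.s + self.repl + self.nes
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"triplet must sum to 1, got {total}")


@dataclass
class LCBDResult:
    site_ids: list[str]
    lcbd: np.ndarray
    sstotal: float
    bdtotal: float
    excluded_sites: list[str] = field(default_factory=list)
    p_values: np.ndarray | None = None
    n_permutations: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"site_id": self.site_ids, "lcbd": self.lcbd})
        if self.p_values is not None:
            df["p_value"] = self.p_values
        return df


def aggregate_to_grid(rng: BinaryRange, grid: GridSystem) -> np.ndarray:
    """Per-site presence vector of one species' binary range (union rule)."""
    vec = grid.aggregate(rng.mask)
    if not vec.any() and rng.area_cells > 0:
        warnings.warn(f"species {rng.species_id!r}: range does not overlap the region mask")
    return vec


def build_pa_matrix(ranges: dict[str, BinaryRange], grid: GridSystem,
                    tag=None) -> PresenceAbsenceMatrix:
    data = {sid: aggregate_to_grid(r, grid) for sid, r in ranges.items()}
    df = pd.DataFrame(data, index=grid.site_ids)
    return PresenceAbsenceMatrix(data=df, tag=tag)


def richness(pa: PresenceAbsenceMatrix) -> pd.Series:
    """Per-site species richness (row sums)."""
    return pa.data.sum(axis=1).astype(int)


def richness_change(current: pd.Series, future: pd.Series) -> pd.DataFrame:
    """Per-site signed richness change and gain/loss/stable class."""
    if not current.index.equals(future.index):
        raise ValueError("current and future richness must index the same sites")
    delta = (future - current).astype(int)
    cls = pd.Series(np.where(delta > 0, "gain", np.where(delta < 0, "loss", "stable")),
                    index=delta.index)
    return pd.DataFrame({"delta": delta, "class": cls})


def paired_t(current: np.ndarray, future: np.ndarray) -> tuple[float, float, int]:
    """Classical paired t test on per-site differences (two-sided)."""
    cur = np.asarray(current, dtype=float)
    fut = np.asarray(future, dtype=float)
    if cur.shape != fut.shape or cur.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal-length")
    if len(cur) < 2:
        raise ValueError("need at least 2 sites")
    diffs = fut - cur
    if np.ptp(diffs) == 0:
        raise ValueError("all paired differences are equal; t statistic undefined")
    res = stats.ttest_rel(fut, cur)
    return float(res.statistic), float(res.pvalue), len(cur) - 1


def pair_counts(x: np.ndarray, y: np.ndarray) -> PairCounts:
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    return PairCounts(a=int(np.sum(x & y)), b=int(np.sum(x & ~y)), c=int(np.sum(~x & y)))


def jaccard_d(p: PairCounts) -> float:
    """Jaccard dissimilarity D = (b+c)/(a+b+c)."""
    denom = p.a + p.b + p.c
    if denom == 0:
        raise ValueError("Jaccard dissimilarity undefined for two empty sites")
    return (p.b + p.c) / denom


def decompose_pair(p: PairCounts) -> BetaTriplet:
    """Baselga-family replacement/nestedness split of the Jaccard
    dissimilarity: Repl = 2·min(b,c)/(a+2·min(b,c)), Nes = D - Repl."""
    d = jaccard_d(p)
    m = min(p.b, p.c)
    repl = 0.0 if m == 0 else 2.0 * m / (p.a + 2.0 * m)
    nes = d - repl
    if nes < 0:  # floating-point guard; analytically Nes >= 0
        nes = 0.0
        repl = d
    return BetaTriplet(s=1.0 - d, repl=repl, nes=nes)


def _abc_matrices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xi = x.astype(np.int64)
    a = xi @ xi.T
    rich = xi.sum(axis=1)
    b = rich[:, None] - a
    c = rich[None, :] - a
    return a, b, c


def jaccard_matrix(x: np.ndarray) -> np.ndarray:
    """Condensed Jaccard dissimilarity over site rows (boolean matrix).

    A pair of empty sites contributes 0 (identical compositions); this case
    only arises inside permutation nulls, observed matrices exclude empty
    sites beforehand.
    """
    return pdist(np.asarray(x, dtype=bool), metric="jaccard")


def decompose_matrix(pa: PresenceAbsenceMatrix) -> pd.DataFrame:
    """(S, Repl, Nes) triplet for every site pair."""
    x = pa.values
    a, b, c = _abc_matrices(x)
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    av, bv, cv = a[iu], b[iu], c[iu]
    tot = av + bv + cv
    if np.any(tot == 0):
        raise ValueError("empty site pair; exclude empty sites first")
    d = (bv + cv) / tot
    m = np.minimum(bv, cv)
    with np.errstate(invalid="ignore", divide="ignore"):
        repl = np.where(m > 0, 2 * m / (av + 2 * m), 0.0)
    nes = np.clip(d - repl, 0.0, None)
    sites = np.asarray(pa.site_ids)
    return pd.DataFrame({"site_i": sites[iu[0]], "site_j": sites[iu[1]],
                         "S": 1.0 - d, "Repl": repl, "Nes": nes})


def _lcbd_core(x: np.ndarray) -> tuple[np.ndarray, float]:
    """LCBD vector and SStotal from a boolean sites × species matrix.

    Builds the Jaccard D, squares it, and double-centers A = -D²/2; the
    diagonal of G over its trace is the LCBD.
    """
    d2 = squareform(jaccard_matrix(x)) ** 2
    n = d2.shape[0]
    a = -0.5 * d2
    h = np.eye(n) - np.ones((n, n)) / n
    g = h @ a @ h
    sstotal = float(np.trace(g))
    return np.diag(g).copy(), sstotal


def lcbd(pa: PresenceAbsenceMatrix | np.ndarray) -> LCBDResult:
    """Local contributions to beta diversity from the Jaccard matrix.

    Empty sites are excluded (and recorded) before computing D. Raises if all
    retained sites share one composition (SStotal = 0, LCBD undefined).
    """
    if isinstance(pa, PresenceAbsenceMatrix):
        x = pa.values
        site_ids = list(pa.site_ids)
    else:
        x = np.asarray(pa, dtype=bool)
        site_ids = [f"s{i:04d}" for i in range(x.shape[0])]
    occupied = x.any(axis=1)
    excluded = [sid for sid, ok in zip(site_ids, occupied) if not ok]
    x = x[occupied]
    kept = [sid for sid, ok in zip(site_ids, occupied) if ok]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 non-empty sites")
    diag, sstotal = _lcbd_core(x)
    if sstotal <= 0:
        raise ValueError("all sites have identical composition; LCBD undefined")
    return LCBDResult(site_ids=kept, lcbd=diag / sstotal, sstotal=sstotal,
                      bdtotal=sstotal / (x.shape[0] - 1), excluded_sites=excluded)


def lcbd_permutation_test(pa: PresenceAbsenceMatrix | np.ndarray, n_perm: int = 999,
                          seed: int = 0) -> LCBDResult:
    """Site-wise LCBD significance under independent-species permutations.

    Each permutation shuffles every species column independently across
    sites; p_i = (1 + #{LCBD*_i >= LCBD_i}) / (1 + n_valid) (add-one
    Monte-Carlo estimator, never exactly 0). Permutations with SStotal = 0
    are skipped and counted.
    """
    base = lcbd(pa)
    if isinstance(pa, PresenceAbsenceMatrix):
        x = pa.values[pa.data.any(axis=1).to_numpy()]
    else:
        x = np.asarray(pa, dtype=bool)
        x = x[x.any(axis=1)]
    rng = np.random.default_rng(seed)
    count_ge = np.zeros(len(base.lcbd))
    n_valid = 0
    for _ in range(n_perm):
        xp = rng.permuted(x, axis=0)  # independent shuffle per species column
        diag, sstotal = _lcbd_core(xp)
        if sstotal <= 0:
            continue
        n_valid += 1
        count_ge += (diag / sstotal) >= (base.lcbd - 1e-12)
    base.p_values = (1.0 + count_ge) / (1.0 + n_valid)
    base.n_permutations = n_valid
    base.seed = seed
    return base


def mean_triplet(triplets: pd.DataFrame | np.ndarray) -> BetaTriplet:
    """Componentwise mean (the ternary-plot centroid); still sums to 1."""
    if isinstance(triplets, pd.DataFrame):
        arr = triplets[["S", "Repl", "Nes"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(triplets, dtype=float).reshape(-1, 3)
    if len(arr) == 0:
        raise ValueError("need at least one triplet")
    s, repl, nes = arr.mean(axis=0)
    return BetaTriplet(s=s, repl=repl, nes=nes)


def ternary_coords(t: BetaTriplet) -> tuple[float, float]:
    """Planar coordinates inside the triangle with vertices Repl = (0, 0),
    Nes = (1, 0), S = (1/2, √3/2)."""
    x = t.nes + t.s / 2.0
    y = t.s * np.sqrt(3.0) / 2.0
    return float(x), float(y)
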