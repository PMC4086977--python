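"""Community-level functional composition and diversity metrics.

Three metrics summarise each plot-year community against the coded trait
table:

* CWM — community-weighted mean of a trait, ``sum_i p_i x_i``;
* Rao's quadratic entropy ``Q = sum_i sum_j p_i p_j d_ij`` over ordered pairs
  (equivalently ``2 sum_{i<j}``), combining functional richness and
  divergence;
* FEve — functional evenness: the regularity of abundance along the minimum
  spanning tree (MST) of the present species in trait space, bounded [0, 1]
  and undefined for fewer than three species.

Species-species dissimilarity is the weighted Gower distance: per-trait
absolute differences normalised by the trait's range over the full species
pool (so distances are comparable across plot-years), averaged with the trait
weights.  Metrics are computed for the full trait suite and for single leaf
traits (notably SLA and LDMC); for a single trait the MST degenerates to the
sorted-neighbour chain, which is exploited for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traits import TraitTable

__all__ = [
    "DistanceMatrix",
    "FDProfile",
    "gower_distance",
    "cwm",
    "rao_q",
    "feve",
    "fd_profile",
    "validate_community",
]

#: FEve needs at least this many species with positive abundance.
FEVE_MIN_SPECIES = 3


@dataclass
class DistanceMatrix:
    """Symmetric species x species Gower dissimilarity in [0, 1]."""

    values: np.ndarray
    species: list[str]
    traits: list[str]
    weights: dict[str, float]
    constant_traits: list[str] = field(default_factory=list)

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        if d.shape != (len(self.species), len(self.species)):
            raise ValueError("distance matrix shape does not match species list")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (d < -1e-12).any() or (d > 1 + 1e-9).any():
            raise ValueError("Gower distances must lie in [0, 1]")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("self-distances must be zero")
        self.values = d


def validate_community(community: pd.DataFrame, tol: float = 1e-9) -> None:
    """Check a plot-year x species relative-abundance matrix."""
    p = community.to_numpy(dtype=float)
    if (p < -tol).any():
        raise ValueError("relative abundances must be nonnegative")
    sums = p.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
    if bad.size:
        raise ValueError(
            f"{bad.size} community rows do not sum to 1 "
            f"(first offender {community.index[bad[0]]!r}, sum={sums[bad[0]]:.6f})"
        )


def gower_distance(
    traits: TraitTable,
    subset: list[str] | None = None,
    weights: dict[str, float] | None = None,
) -> DistanceMatrix:
    """Weighted Gower dissimilarity over the species pool.

    d_ij = sum_k w_k |x_ik - x_jk| / range_k / sum_k w_k, with per-trait
    ranges taken over the full pool.  Traits constant across the pool carry no
    information; they are dropped from the sum and reported in
    ``constant_traits``.  All traits constant is an error.
    """
    names = list(subset) if subset is not None else traits.trait_names
    if not names:
        raise ValueError("trait subset must be nonempty")
    if weights is None:
        weights = traits.weights(names)
    x = traits.data[names].to_numpy(dtype=float)
    rng = x.max(axis=0) - x.min(axis=0)
    keep = rng > 0
    constant = [n for n, k in zip(names, keep) if not k]
    if not keep.any():
        raise ValueError(f"zero trait variation: all of {names} constant across the pool")
    w = np.array([weights[n] for n in names])[keep]
    xk = x[:, keep] / rng[keep]
    # |x_i - x_j| summed with weights, vectorised over species pairs
    diff = np.abs(xk[:, None, :] - xk[None, :, :])
    d = (diff * w).sum(axis=2) / w.sum()
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # enforce exact symmetry against fp noise
    return DistanceMatrix(
        values=d,
        species=traits.species,
        traits=[n for n in names if n not in constant],
        weights={n: weights[n] for n in names},
        constant_traits=constant,
    )


def cwm(abund: np.ndarray | pd.Series, traits: TraitTable, trait: str) -> float:
    """Community-weighted mean of one trait: sum_i p_i x_i."""
    x = traits.values_for(trait)
    if isinstance(abund, pd.Series):
        missing = set(abund.index) - set(x.index)
        if missing:
            raise ValueError(f"community species absent from trait table: {sorted(missing)}")
        x = x.reindex(abund.index)
        p = abund.to_numpy(dtype=float)
    else:
        p = np.asarray(abund, dtype=float)
        if p.shape[0] != len(x):
            raise ValueError("abundance vector length does not match trait table species")
    return float(p @ x.to_numpy(dtype=float))


def rao_q(abund: np.ndarray, d: DistanceMatrix | np.ndarray) -> float:
    """Rao's quadratic entropy Q = p . D . p over ordered pairs."""
    p = np.asarray(abund, dtype=float)
    dm = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if p.shape[0] != dm.shape[0]:
        raise ValueError(
            f"abundance length {p.shape[0]} does not match distance matrix {dm.shape[0]}"
        )
    return float(p @ dm @ p)


def _mst_edges_kruskal(d: np.ndarray) -> list[tuple[int, int]]:
    """Kruskal MST with deterministic lexicographic tie-breaks.

    Candidate edges are processed in increasing (length, i, j) order so equal
    length ties always resolve to the same tree — FEve is tie-sensitive.
    """
    n = d.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, d[iu, ju]))
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges: list[tuple[int, int]] = []
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j))
            if len(edges) == n - 1:
                break
    return edges


def _feve_from_mst(p: np.ndarray, d: np.ndarray, edges: list[tuple[int, int]]) -> float:
    s = p.shape[0]
    ew = np.array([d[i, j] / (p[i] + p[j]) for i, j in edges])
    total = ew.sum()
    if total == 0:
        # all present species functionally identical: perfectly even tree
        return 1.0
    pew = ew / total
    thr = 1.0 / (s - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def feve(
    abund: np.ndarray,
    d: DistanceMatrix | np.ndarray,
    *,
    one_dimensional: np.ndarray | None = None,
) -> float | None:
    """Functional evenness of the present species along the trait-space MST.

    For each MST branch joining species i, j the abundance-discounted length
    is EW = d_ij / (p_i + p_j); with PEW = EW / sum(EW) and S present species,

        FEve = (sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1)).

    Returns None (undefined) when fewer than three species have positive
    abundance.  ``one_dimensional`` may supply the present species' positions
    on a single trait axis, in which case the MST is the sorted-neighbour
    chain and no quadratic edge search is needed.
    """
    p = np.asarray(abund, dtype=float)
    # abundances below any realistic sampling resolution are treated as absent
    present = np.flatnonzero(p > 1e-12)
    if present.size < FEVE_MIN_SPECIES:
        return None
    pp = p[present]
    pp = pp / pp.sum()
    dm = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    dsub = dm[np.ix_(present, present)]
    if one_dimensional is not None:
        pos = np.asarray(one_dimensional, dtype=float)[present]
        order = np.argsort(pos, kind="stable")
        edges = [(int(order[k]), int(order[k + 1])) for k in range(order.size - 1)]
    else:
        edges = _mst_edges_kruskal(dsub)
    return _feve_from_mst(pp, dsub, edges)


@dataclass
class FDProfile:
    """Per plot-year functional composition summary.

    ``feve_*`` entries are None where undefined (fewer than three species
    present); the flag is carried, never silently dropped.
    """

    row_key: object
    cwm: dict[str, float]
    rao_all: float
    feve_all: float | None
    rao_trait: dict[str, float]
    feve_trait: dict[str, float | None]
    rao_trait_raw: dict[str, float]
    n_species_present: int

    def to_flat_dict(self) -> dict[str, object]:
        out: dict[str, object] = {"row_key": self.row_key, "n_species": self.n_species_present}
        out.update({f"cwm_{t}": v for t, v in self.cwm.items()})
        out["rao_all"] = self.rao_all
        out["feve_all"] = self.feve_all
        out.update({f"rao_{t}": v for t, v in self.rao_trait.items()})
        out.update({f"feve_{t}": v for t, v in self.feve_trait.items()})
        out.update({f"rao_raw_{t}": v for t, v in self.rao_trait_raw.items()})
        return out


def fd_profile(
    community: pd.DataFrame,
    traits: TraitTable,
    single_traits: tuple[str, ...] = ("sla_mm2_per_mg", "ldmc_mg_per_g"),
    cwm_traits: tuple[str, ...] | None = None,
    compute_feve: bool = True,
) -> list[FDProfile]:
    """Full FD profile for every row of a community matrix.

    Rao and FEve are computed over the full trait suite and for each trait in
    ``single_traits`` separately.  Single-trait Rao is reported both on the
    range-normalised Gower scale (comparable to the full-suite value) and in
    raw trait units.  ``compute_feve=False`` skips the MST-based metric for
    speed when only Rao/CWM are needed.
    """
    validate_community(community)
    species = list(community.columns)
    extra = set(species) - set(traits.species)
    if extra:
        raise ValueError(f"community species absent from trait table: {sorted(extra)}")
    if species != traits.species:
        # the community's species define the pool; align trait rows to it
        traits = TraitTable(data=traits.data.loc[species], schemes=traits.schemes)

    d_all = gower_distance(traits)
    P = community.to_numpy(dtype=float)
    X = {t: traits.values_for(t).to_numpy(dtype=float) for t in traits.trait_names}

    singles: dict[str, tuple[np.ndarray, float]] = {}
    for t in single_traits:
        x = X[t]
        rng = x.max() - x.min()
        if rng <= 0:
            raise ValueError(f"zero trait variation: single trait {t!r} constant across pool")
        singles[t] = (x, rng)

    cwm_names = list(cwm_traits) if cwm_traits is not None else traits.trait_names

    # Rao vectorised over rows: p D p^T for all rows at once
    rao_all_vec = np.einsum("ri,ij,rj->r", P, d_all.values, P)
    rao_single_vec = {}
    for t, (x, rng) in singles.items():
        dx = np.abs(x[:, None] - x[None, :])
        rao_raw = np.einsum("ri,ij,rj->r", P, dx, P)
        rao_single_vec[t] = (rao_raw / rng, rao_raw)

    profiles: list[FDProfile] = []
    for r, key in enumerate(community.index):
        p = P[r]
        cwm_vals = {t: float(p @ X[t]) for t in cwm_names}
        n_present = int((p > 0).sum())
        if compute_feve:
            feve_all = feve(p, d_all)
            feve_tr = {
                t: feve(p, np.abs(x[:, None] - x[None, :]) / rng, one_dimensional=x)
                for t, (x, rng) in singles.items()
            }
        else:
            feve_all = None
            feve_tr = {t: None for t in singles}
        profiles.append(
            FDProfile(
                row_key=key,
                cwm=cwm_vals,
                rao_all=float(rao_all_vec[r]),
                feve_all=feve_all,
                rao_trait={t: float(rao_single_vec[t][0][r]) for t in singles},
                feve_trait=feve_tr,
                rao_trait_raw={t: float(rao_single_vec[t][1][r]) for t in singles},
                n_species_present=n_present,
            )
        )
    return profiles


def profiles_to_frame(profiles: list[FDProfile]) -> pd.DataFrame:
    """Tidy one-row-per-plot-year DataFrame of FD metrics."""
    return pd.DataFrame([p.to_flat_dict() for p in profiles]).set_index("row_key")
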