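"""Relative abundance, distributional breadth, and spatial co-occurrence.

All indices are computed from a species' *usage distribution* across camera
sites: P_ij, the share of species i's independent events recorded at site j.

* RAI_i = 100 · n_i / Σ n_i — a species' percent share of the community's
  independent detections; species with RAI above the community mean (100/S)
  pass the abundance screen used to choose the association-analysis set.
* Levins breadth B_L = 1/Σ_j P_ij² ∈ [1, r] (inverse Simpson concentration).
* Shannon breadth B_S = −Σ_j P_ij ln P_ij ∈ [0, ln r].
* Pianka overlap O_ik = Σ P_ij P_kj / sqrt(Σ P_ij² Σ P_kj²) ∈ [0, 1] — the
  cosine similarity of two species' site-usage vectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detections import SiteSpeciesMatrix

__all__ = [
    "usage_distribution",
    "rai_table",
    "levins_breadth",
    "shannon_breadth",
    "breadth_table",
    "pianka_overlap",
    "overlap_matrix",
    "overlap_pairs",
]


def usage_distribution(counts) -> np.ndarray:
    """Normalise per-site counts of one species to shares P_ij (sum 1)."""
    p = np.asarray(counts, dtype=float)
    if (p < 0).any():
        raise ValueError("usage counts must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("species has zero events; usage distribution undefined")
    return p / total


def rai_table(event_counts: pd.Series) -> pd.DataFrame:
    """Relative abundance table with the mean-threshold screen.

    Parameters
    ----------
    event_counts : per-species independent-event counts n_i (index = species).

    Returns a DataFrame (index = species) with columns ``n_events``, ``rai``
    (percent, sums to 100), and ``selected`` (strictly above the community
    mean 100/S; ties with the mean are not selected).
    """
    n = pd.Series(event_counts).astype(float)
    if (n < 0).any():
        raise ValueError("event counts must be non-negative")
    total = n.sum()
    if total == 0:
        raise ValueError("all event counts are zero")
    rai = 100.0 * n / total
    mean = 100.0 / len(n)
    return pd.DataFrame(
        {"n_events": n.astype(int), "rai": rai, "selected": rai > mean},
        index=n.index.rename("species"),
    )


def levins_breadth(usage) -> float:
    """Levins distributional breadth B_L = 1/Σ P_ij² (∈ [1, r])."""
    p = usage_distribution(usage)
    return 1.0 / float(np.sum(p * p))


def shannon_breadth(usage) -> float:
    """Shannon distributional breadth B_S = −Σ P_ij ln P_ij, with 0·ln 0 = 0."""
    p = usage_distribution(usage)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def breadth_table(matrix: SiteSpeciesMatrix) -> pd.DataFrame:
    """Per-species B_L and B_S over the site dimension (NaN for zero-event species)."""
    rows = {}
    for i, sp in enumerate(matrix.species):
        col = matrix.counts[:, i]
        if col.sum() == 0:
            rows[sp] = (np.nan, np.nan)
        else:
            rows[sp] = (levins_breadth(col), shannon_breadth(col))
    return pd.DataFrame.from_dict(rows, orient="index", columns=["B_L", "B_S"]).rename_axis("species")


def pianka_overlap(usage_i, usage_k) -> float:
    """Pianka spatial co-occurrence index O_ik (cosine of count vectors).

    Scale-invariant in either argument, so raw counts are accepted.
    1 = identical site usage, 0 = disjoint site sets.
    """
    pi = np.asarray(usage_i, dtype=float)
    pk = np.asarray(usage_k, dtype=float)
    if pi.shape != pk.shape:
        raise ValueError("usage vectors must share the same site ordering/length")
    if (pi < 0).any() or (pk < 0).any():
        raise ValueError("usage must be non-negative")
    ni = np.sqrt(np.sum(pi * pi))
    nk = np.sqrt(np.sum(pk * pk))
    if ni == 0 or nk == 0:
        raise ValueError("species with zero events; overlap undefined")
    return float(np.sum(pi * pk) / (ni * nk))


def overlap_matrix(matrix: SiteSpeciesMatrix) -> pd.DataFrame:
    """Symmetric S × S Pianka matrix, diagonal 1; NaN rows for zero-event species."""
    X = matrix.counts.astype(float)
    norms = np.sqrt((X * X).sum(axis=0))
    S = matrix.n_species
    O = np.full((S, S), np.nan)
    ok = norms > 0
    G = X.T @ X
    denom = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = G / denom
    O[np.ix_(ok, ok)] = vals[np.ix_(ok, ok)]
    np.fill_diagonal(O, np.where(ok, 1.0, np.nan))
    return pd.DataFrame(O, index=matrix.species, columns=matrix.species)


def overlap_pairs(matrix: SiteSpeciesMatrix) -> pd.DataFrame:
    """Long-format upper-triangle Pianka pairs (species_a, species_b, pianka)."""
    O = overlap_matrix(matrix)
    rows = []
    sp = list(O.index)
    for i in range(len(sp)):
        for k in range(i + 1, len(sp)):
            rows.append((sp[i], sp[k], O.iloc[i, k]))
    return pd.DataFrame(rows, columns=["species_a", "species_b", "pianka"])
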