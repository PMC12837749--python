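"""Interspecific association statistics on presence–absence data.

Community level
    Schluter's variance ratio V_R compares the variance of per-site species
    richness T_j with its expectation under independent occurrences,
    Σ_i p_i(1−p_i) where p_i is species i's occupancy rate.  V_R = 1 under
    independence, > 1 for net positive association.  Its test statistic
    W = V_R · N is referred to a two-sided chi-square band.

Pairwise level
    From the 2 × 2 presence table (a = both, b = only A, c = only B,
    d = neither) the Phi coefficient φ = (ad−bc)/√((a+b)(a+c)(b+d)(c+d))
    measures signed association, tested with the Yates continuity-corrected
    chi-square against the df = 1 critical values 3.841 (p = 0.05) and
    6.635 (p = 0.01).

Asymmetric predictability
    The Goodman–Kruskal lambda gives the proportional reduction in error in
    predicting one species' presence state from the other's; it is
    directional, and its bootstrap limits (L_B upper, λ_BO lower) quantify
    one-way "commensal" dependence: λ_BO > 0 flags significant asymmetric
    association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "PairAssociation",
    "CommunityAssociation",
    "LambdaAssociation",
    "CHI2_P05",
    "CHI2_P01",
    "contingency",
    "phi",
    "yates_chi2",
    "classify_chi2",
    "association_sign",
    "pair_association",
    "variance_ratio",
    "gk_lambda",
    "pairwise_association_table",
    "lambda_table",
]

#: df = 1 chi-square critical values at p = 0.05 and p = 0.01.
CHI2_P05: float = float(stats.chi2.ppf(0.95, df=1))
CHI2_P01: float = float(stats.chi2.ppf(0.99, df=1))


@dataclass(frozen=True)
class ContingencyTable:
    """2 × 2 presence table: a = both, b = only A, c = only B, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(a+b, c+d, a+c, b+d): A present/absent, B present/absent."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class PairAssociation:
    species_a: str
    species_b: str
    table: ContingencyTable
    phi: float
    chi2_yates: float
    significance: str  # none | significant | highly_significant
    sign: str  # positive | negative | independent


@dataclass(frozen=True)
class CommunityAssociation:
    vr: float
    w: float
    df: int
    band: tuple[float, float]  # (chi2_{0.95}, chi2_{0.05}) quantiles at df
    verdict: str  # significant_positive | significant_negative | not_significant


@dataclass(frozen=True)
class LambdaAssociation:
    predictor: str
    predicted: str
    lam: float
    l_b: float  # upper limit of the prediction rate
    lambda_bo: float  # lower limit
    p: float  # from the Yates chi-square of the same table
    significant: bool  # lambda_bo > 0


def contingency(presence_a, presence_b) -> ContingencyTable:
    """Cross-tabulate two boolean site vectors into the 2 × 2 presence table."""
    pa = np.asarray(presence_a, dtype=bool)
    pb = np.asarray(presence_b, dtype=bool)
    if pa.shape != pb.shape or pa.ndim != 1:
        raise ValueError("presence vectors must be 1-D and of equal length")
    return ContingencyTable(
        a=int(np.sum(pa & pb)),
        b=int(np.sum(pa & ~pb)),
        c=int(np.sum(~pa & pb)),
        d=int(np.sum(~pa & ~pb)),
    )


def _check_margins(t: ContingencyTable) -> None:
    if min(t.margins) == 0:
        raise ValueError(
            "degenerate 2x2 table (a zero margin: one species present at all "
            "or no sites); phi/chi-square undefined"
        )


def phi(t: ContingencyTable) -> float:
    """Phi coefficient (ad−bc)/√((a+b)(a+c)(b+d)(c+d)) ∈ [−1, 1]."""
    _check_margins(t)
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    denom = np.sqrt((a + b) * (a + c) * (b + d) * (c + d))
    return float((a * d - b * c) / denom)


def yates_chi2(t: ContingencyTable) -> float:
    """Continuity-corrected chi-square n(|ad−bc| − n/2)₊² / Π margins.

    The corrected numerator is clamped at zero when |ad−bc| ≤ n/2, keeping
    the statistic zero for tables at or inside the correction band.
    """
    _check_margins(t)
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    n = a + b + c + d
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    denom = (a + b) * (a + c) * (b + d) * (c + d)
    return float(n * num * num / denom)


def classify_chi2(chi2: float) -> str:
    """Significance class from the df = 1 critical values (strict inequalities)."""
    if chi2 < 0:
        raise ValueError("chi-square must be non-negative")
    if chi2 > CHI2_P01:
        return "highly_significant"
    if chi2 > CHI2_P05:
        return "significant"
    return "none"


def association_sign(t: ContingencyTable) -> str:
    """Direction of association from the cross-product ad − bc."""
    cross = t.a * t.d - t.b * t.c
    if cross > 0:
        return "positive"
    if cross < 0:
        return "negative"
    return "independent"


def pair_association(species_a: str, species_b: str, presence_a, presence_b) -> PairAssociation:
    """Full pairwise association: table, φ, Yates χ², class, and sign."""
    t = contingency(presence_a, presence_b)
    return PairAssociation(
        species_a=species_a,
        species_b=species_b,
        table=t,
        phi=phi(t),
        chi2_yates=yates_chi2(t),
        significance=classify_chi2(yates_chi2(t)),
        sign=association_sign(t),
    )


def variance_ratio(presence, df: int | None = None, alpha: float = 0.05) -> CommunityAssociation:
    """Schluter variance-ratio test of community-wide association.

    Parameters
    ----------
    presence : r × S boolean matrix (sites × species).
    df : degrees of freedom for the chi-square band; defaults to N, the
        number of sites.
    alpha : two-sided band level (default 0.05 → the 43.19–79.08-style
        (χ²_{0.95}, χ²_{0.05}) band).

    V_R = [(1/N) Σ_j (T_j − t̄)²] / [Σ_i p_i (1 − p_i)]; W = V_R · N.
    W inside the band → 'not_significant'; outside → 'significant_positive'
    if V_R > 1 else 'significant_negative'.
    """
    P = np.asarray(presence, dtype=bool)
    if P.ndim != 2 or P.shape[0] < 2 or P.shape[1] < 2:
        raise ValueError("presence matrix must be r × S with r ≥ 2 and S ≥ 2")
    N = P.shape[0]
    p_i = P.mean(axis=0)
    denom = float(np.sum(p_i * (1 - p_i)))
    if denom == 0:
        raise ValueError("all species occur at all sites or none; variance ratio undefined")
    T = P.sum(axis=1)
    num = float(np.mean((T - T.mean()) ** 2))
    vr = num / denom
    if df is None:
        df = N
    lo = float(stats.chi2.ppf(alpha, df))
    hi = float(stats.chi2.ppf(1 - alpha, df))
    w = vr * N
    if lo < w < hi:
        verdict = "not_significant"
    else:
        verdict = "significant_positive" if vr > 1 else "significant_negative"
    return CommunityAssociation(vr=vr, w=w, df=df, band=(lo, hi), verdict=verdict)


def _lambda_point(a: float, b: float, c: float, d: float) -> float:
    """GK lambda predicting B's state (columns) from A's state (rows)."""
    n = a + b + c + d
    max_col_margin = max(a + c, b + d)
    denom = n - max_col_margin
    if denom == 0:
        raise ValueError("predicted species has a constant state; lambda undefined")
    return (max(a, b) + max(c, d) - max_col_margin) / denom


def gk_lambda(
    t: ContingencyTable,
    predictor: str = "A",
    predicted: str = "B",
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> LambdaAssociation:
    """Goodman–Kruskal asymmetric lambda with bootstrap prediction-rate limits.

    Predicts the ``predicted`` species' presence state from the
    ``predictor``'s.  The table is oriented with species A on rows; pass
    ``predictor="B"`` to predict A from B (transposes the table).  The upper
    (L_B) and lower (λ_BO) limits come from a site-resampling bootstrap using
    the basic (reversed-percentile) 95% interval, which — unlike a plain
    percentile interval — can drop below zero for weak associations.  A
    significant one-way dependence is declared when λ_BO > 0.  The p-value
    is from the Yates chi-square of the same table.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    if predictor == predicted:
        raise ValueError("predictor and predicted must differ")
    # orient: rows = predictor states, columns = predicted states
    if predictor == "A":
        a, b, c, d = t.a, t.b, t.c, t.d
    else:
        a, b, c, d = t.a, t.c, t.b, t.d  # transpose
    lam = _lambda_point(a, b, c, d)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = a + b + c + d
    probs = np.array([a, b, c, d], dtype=float) / n
    cells = rng.multinomial(n, probs, size=n_boot).astype(float)
    maxrow = np.maximum(cells[:, 0], cells[:, 1]) + np.maximum(cells[:, 2], cells[:, 3])
    colmax = np.maximum(cells[:, 0] + cells[:, 2], cells[:, 1] + cells[:, 3])
    denom = n - colmax
    ok = denom > 0
    lam_boot = np.where(ok, (maxrow - colmax) / np.where(ok, denom, 1.0), 0.0)
    q_lo, q_hi = np.quantile(lam_boot, [0.025, 0.975])
    # basic (reversed-percentile) interval; widened to cover the point estimate
    lower = min(2 * lam - q_hi, lam)
    upper = max(2 * lam - q_lo, lam)
    p = float(stats.chi2.sf(yates_chi2(t), df=1))
    return LambdaAssociation(
        predictor=predictor,
        predicted=predicted,
        lam=float(lam),
        l_b=float(upper),
        lambda_bo=float(lower),
        p=p,
        significant=bool(lower > 0),
    )


def pairwise_association_table(matrix, species: list[str] | None = None) -> pd.DataFrame:
    """All-pairs φ / Yates χ² table over (a subset of) a SiteSpeciesMatrix.

    Pairs with a zero margin (a species at every or no site) are reported
    with NaN statistics and class 'undefined'.
    """
    sp = species if species is not None else list(matrix.species)
    missing = [s for s in sp if s not in matrix.species]
    if missing:
        raise KeyError(f"species not in matrix: {missing}")
    pres = {s: matrix.presence[:, matrix.species.index(s)] for s in sp}
    rows = []
    for i in range(len(sp)):
        for k in range(i + 1, len(sp)):
            sa, sb = sp[i], sp[k]
            t = contingency(pres[sa], pres[sb])
            try:
                ph, ch = phi(t), yates_chi2(t)
                cls = classify_chi2(ch)
            except ValueError:
                ph, ch, cls = np.nan, np.nan, "undefined"
            rows.append((sa, sb, t.a, t.b, t.c, t.d, ph, ch, association_sign(t), cls))
    return pd.DataFrame(
        rows,
        columns=["species_a", "species_b", "a", "b", "c", "d", "phi", "chi2_yates", "sign", "class"],
    )


def lambda_table(
    matrix,
    focal: str,
    partners: list[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Directed lambda table (both directions) between a focal species and partners."""
    rng = np.random.default_rng(seed)
    pres = {s: matrix.presence[:, matrix.species.index(s)] for s in [focal, *partners]}
    rows = []
    for partner in partners:
        t = contingency(pres[focal], pres[partner])
        for direction, (pred_name, tgt_name) in (("A", (focal, partner)), ("B", (partner, focal))):
            try:
                la = gk_lambda(
                    t,
                    predictor=direction,
                    predicted="B" if direction == "A" else "A",
                    n_boot=n_boot,
                    seed=rng,
                )
                rows.append(
                    (pred_name, tgt_name, la.lam, la.l_b, la.lambda_bo, la.p, la.significant)
                )
            except ValueError:
                rows.append((pred_name, tgt_name, np.nan, np.nan, np.nan, np.nan, False))
    return pd.DataFrame(
        rows,
        columns=["predictor", "predicted", "lambda", "L_B", "lambda_BO", "p", "significant"],
    )
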