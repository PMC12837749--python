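"""Synthetic camera-trap communities with known association structure.

The generator emulates a grid of camera traps monitored over a study window:

* presence — per-site species occurrences drawn from a Gaussian copula:
  a latent multivariate normal per site, thresholded at Φ⁻¹(1 − ψ_i) so each
  species occurs with its occupancy probability ψ_i while pairwise targets
  (latent correlation or a target phi coefficient) are honoured;
* detections — per occupied site, a zero-truncated negative binomial number
  of independent events (mean μ_i, dispersion k_i), each with a calendar
  start drawn uniformly over study days and a time of day from the species'
  von Mises mixture activity profile; event starts of the same
  (site, species) are kept ≥ 31 min apart so the 30-min independence filter
  recovers the planted events exactly, and each event carries 1–several raw
  records within its 30-min window so the filter is exercised nontrivially.

Presets (shipped as YAML under ``camtrapnet/data/presets``) encode three
study designs: ``paper_like`` (67 sites, 12 species, a strong positive pair
and a one-way commensal pair, heterogeneous occupancy, a bimodal crepuscular
focal species), ``null_community`` (fully independent, balanced occupancy for
test-size calibration), and ``strong_pairs`` (a small community with several
planted positive and negative associations).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy import stats
from scipy.optimize import brentq

from .detections import DetectionRecord

__all__ = [
    "SpeciesSpec",
    "CommunitySpec",
    "latent_correlation_for_phi",
    "expected_phi",
    "build_latent_corr",
    "simulate_presence",
    "simulate_detections",
    "write_fixture",
    "load_preset",
    "PRESETS",
]

PRESETS = ("paper_like", "null_community", "strong_pairs")


@dataclass(frozen=True)
class SpeciesSpec:
    """One species: occupancy ψ, detection intensity (μ, k), diel profile.

    ``activity`` is a von Mises mixture given as (weight, mean direction in
    radians, concentration) triples; weights must sum to 1.
    """

    name: str
    psi: float
    mu: float = 5.0
    k: float = 2.0
    activity: tuple[tuple[float, float, float], ...] = ((1.0, np.pi, 0.0),)

    def __post_init__(self) -> None:
        if not 0 < self.psi <= 1:
            raise ValueError(f"{self.name}: psi must be in (0, 1]")
        if self.mu <= 0 or self.k <= 0:
            raise ValueError(f"{self.name}: mu and k must be positive")
        w = sum(c[0] for c in self.activity)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: activity mixture weights must sum to 1")


@dataclass
class CommunitySpec:
    """Full design of a synthetic camera-trap study."""

    n_sites: int
    species: list[SpeciesSpec]
    latent_corr: np.ndarray | None = None  # S × S latent correlation
    start: datetime = field(default_factory=lambda: datetime(2022, 6, 1))
    n_days: int = 365

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be ≥ 1")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        S = len(self.species)
        if self.latent_corr is None:
            self.latent_corr = np.eye(S)
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        if self.latent_corr.shape != (S, S):
            raise ValueError("latent_corr must be S × S")
        if not np.allclose(self.latent_corr, self.latent_corr.T):
            raise ValueError("latent_corr must be symmetric")
        if not np.allclose(np.diag(self.latent_corr), 1.0):
            raise ValueError("latent_corr must have unit diagonal")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]


def _bvn_upper(t1: float, t2: float, rho: float) -> float:
    """P(Z1 > t1, Z2 > t2) for standard bivariate normal with correlation rho."""
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    return float(1.0 - stats.norm.cdf(t1) - stats.norm.cdf(t2) + mvn.cdf([t1, t2]))


def expected_phi(psi1: float, psi2: float, rho: float) -> float:
    """Phi coefficient implied by a latent correlation under the copula model."""
    t1 = stats.norm.ppf(1 - psi1)
    t2 = stats.norm.ppf(1 - psi2)
    p11 = _bvn_upper(t1, t2, rho)
    denom = np.sqrt(psi1 * (1 - psi1) * psi2 * (1 - psi2))
    return (p11 - psi1 * psi2) / denom


def latent_correlation_for_phi(psi1: float, psi2: float, phi_target: float) -> float:
    """Invert the copula: the latent rho whose realized phi equals ``phi_target``.

    The attainable phi range for given occupancies is bounded (Fréchet); an
    unattainable target raises ValueError.
    """
    if phi_target == 0:
        return 0.0
    lo, hi = -0.999, 0.999
    f = lambda r: expected_phi(psi1, psi2, r) - phi_target
    if f(lo) * f(hi) > 0:
        raise ValueError(
            f"target phi {phi_target} unattainable for occupancies ({psi1}, {psi2})"
        )
    return float(brentq(f, lo, hi, xtol=1e-6))


def _nearest_psd(R: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= eps:
        return R
    warnings.warn("latent correlation targets jointly infeasible; nearest-PSD repair applied")
    vals = np.clip(vals, eps, None)
    A = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(A))
    return A / np.outer(d, d)


def build_latent_corr(
    species: list[SpeciesSpec],
    pairs: dict[tuple[str, str], dict] | None,
) -> np.ndarray:
    """Latent correlation matrix from pairwise targets.

    ``pairs`` maps (name_a, name_b) to either ``{"latent": rho}`` or
    ``{"phi": target}`` (converted through the copula using the two species'
    occupancies).  Unlisted pairs are independent.
    """
    names = [s.name for s in species]
    psi = {s.name: s.psi for s in species}
    R = np.eye(len(names))
    ix = {n: i for i, n in enumerate(names)}
    for (a, b), target in (pairs or {}).items():
        if a not in ix or b not in ix:
            raise KeyError(f"unknown species in association pair ({a}, {b})")
        if "latent" in target:
            rho = float(target["latent"])
        elif "phi" in target:
            rho = latent_correlation_for_phi(psi[a], psi[b], float(target["phi"]))
        else:
            raise ValueError("pair target must give 'latent' or 'phi'")
        R[ix[a], ix[b]] = R[ix[b], ix[a]] = rho
    return _nearest_psd(R)


def simulate_presence(spec: CommunitySpec, seed: int | np.random.Generator | None = 0) -> np.ndarray:
    """r × S boolean presence matrix from the thresholded Gaussian copula."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R = _nearest_psd(spec.latent_corr)
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((spec.n_sites, len(spec.species))) @ L.T
    thresh = stats.norm.ppf(1 - np.array([s.psi for s in spec.species]))
    return Z > thresh[None, :]


def _ztnb(rng: np.random.Generator, mu: float, k: float, size: int) -> np.ndarray:
    """Zero-truncated negative binomial via inverse-CDF (size = k, mean = mu)."""
    p = k / (k + mu)
    p0 = p**k
    u = rng.uniform(p0, 1.0, size=size)
    return stats.nbinom.ppf(u, k, p).astype(int)


def _mixture_minutes(rng: np.random.Generator, activity, size: int) -> np.ndarray:
    """Time-of-day minutes (0..1439) from a von Mises mixture over the circle."""
    weights = np.array([c[0] for c in activity])
    comp = rng.choice(len(activity), size=size, p=weights / weights.sum())
    out = np.empty(size)
    for i, (_, mu_dir, kappa) in enumerate(activity):
        m = comp == i
        if not m.any():
            continue
        if kappa < 1e-12:
            draws = rng.uniform(0, 2 * np.pi, size=m.sum())
        else:
            draws = np.mod(rng.vonmises(mu_dir, kappa, size=m.sum()), 2 * np.pi)
        out[m] = draws
    return np.floor(out / (2 * np.pi) * 1440).astype(int) % 1440


def _spaced_event_minutes(
    rng: np.random.Generator, sp: SpeciesSpec, n_events: int, n_days: int, min_gap: int = 31
) -> np.ndarray:
    """Absolute study minutes for event starts, pairwise ≥ min_gap apart."""
    for _ in range(1000):
        days = rng.integers(0, n_days, size=n_events)
        tod = _mixture_minutes(rng, sp.activity, n_events)
        minutes = np.sort(days * 1440 + tod)
        if n_events == 1 or np.diff(minutes).min() >= min_gap:
            return minutes
    raise RuntimeError(
        f"could not place {n_events} events ≥ {min_gap} min apart in {n_days} days"
    )


def simulate_detections(
    presence: np.ndarray,
    spec: CommunitySpec,
    seed: int | np.random.Generator | None = 0,
    records_per_event_lambda: float = 0.7,
) -> list[DetectionRecord]:
    """Raw detection records realising a presence matrix.

    Every occupied (site, species) cell receives ≥ 1 independent event; each
    event yields one initial record plus Poisson(``records_per_event_lambda``)
    extra records at 1–29 min offsets, all at minute precision.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P = np.asarray(presence, dtype=bool)
    if P.shape != (spec.n_sites, len(spec.species)):
        raise ValueError("presence shape does not match the community spec")
    site_labels = [f"S{j + 1:03d}" for j in range(spec.n_sites)]
    records: list[DetectionRecord] = []
    for i, sp in enumerate(spec.species):
        for j in np.flatnonzero(P[:, i]):
            n_events = int(_ztnb(rng, sp.mu, sp.k, 1)[0])
            starts = _spaced_event_minutes(rng, sp, n_events, spec.n_days)
            for m in starts:
                t0 = spec.start + timedelta(minutes=int(m))
                records.append(DetectionRecord(site_labels[j], sp.name, t0))
                for off in rng.integers(1, 30, size=rng.poisson(records_per_event_lambda)):
                    records.append(
                        DetectionRecord(site_labels[j], sp.name, t0 + timedelta(minutes=int(off)))
                    )
    records.sort(key=lambda r: (r.site_id, r.species, r.timestamp))
    return records


def write_fixture(
    records: list[DetectionRecord],
    path: str | Path,
    spec: CommunitySpec | None = None,
    seed: int | None = None,
) -> Path:
    """Write records as a detections CSV plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["site_id,species,timestamp\n"]
    for r in records:
        lines.append(f"{r.site_id},{r.species},{r.timestamp.strftime('%Y-%m-%d %H:%M')}\n")
    path.write_text("".join(lines))
    meta: dict = {"n_records": len(records), "seed": seed}
    if spec is not None:
        d = asdict_spec(spec)
        meta["spec"] = d
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    return path


def asdict_spec(spec: CommunitySpec) -> dict:
    return {
        "n_sites": spec.n_sites,
        "n_days": spec.n_days,
        "start": spec.start.strftime("%Y-%m-%d"),
        "species": [asdict(s) for s in spec.species],
        "latent_corr": np.asarray(spec.latent_corr).round(6).tolist(),
    }


def spec_from_dict(d: dict) -> CommunitySpec:
    """Build a CommunitySpec from a preset/config mapping (see data/presets)."""
    species = [
        SpeciesSpec(
            name=s["name"],
            psi=float(s["psi"]),
            mu=float(s.get("mu", 5.0)),
            k=float(s.get("k", 2.0)),
            activity=tuple(tuple(float(x) for x in c) for c in s.get("activity", [[1.0, np.pi, 0.0]])),
        )
        for s in d["species"]
    ]
    pairs = {}
    for item in d.get("associations", []) or []:
        a, b = item["pair"]
        target = {k: v for k, v in item.items() if k in ("latent", "phi")}
        pairs[(a, b)] = target
    R = build_latent_corr(species, pairs) if pairs else None
    start = d.get("start", "2022-06-01")
    if isinstance(start, str):
        start = datetime.strptime(start, "%Y-%m-%d")
    elif not isinstance(start, datetime):
        start = datetime(start.year, start.month, start.day)
    return CommunitySpec(
        n_sites=int(d["n_sites"]),
        species=species,
        latent_corr=R,
        start=start,
        n_days=int(d.get("n_days", 365)),
    )


def load_preset(name: str) -> CommunitySpec:
    """Load one of the shipped study designs: paper_like, null_community, strong_pairs."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESETS}")
    ref = resources.files("camtrapnet.data").joinpath(f"presets/{name}.yaml")
    return spec_from_dict(yaml.safe_load(ref.read_text()))
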