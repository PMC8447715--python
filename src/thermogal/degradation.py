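"""Galactan degradation-profile quantification and Michaelis-Menten kinetics.

A digest sample holds the oligosaccharide concentrations G1..G5 (mM, as from
anion-exchange chromatography) and the total reducing-end concentration (mM,
as from a colorimetric reducing-end assay). From these the module derives:

* the degree of hydrolysis (DoH): reducing ends over the theoretical maximum
  reached at full degradation to galactose,
* a rough estimate of oligosaccharides longer than G5, by mass balance:
  every chain carries one reducing end, so reducing ends minus the measured
  G1..G5 chains counts the longer chains,
* small-integer endpoint molar ratios of accumulated products, and
* Michaelis-Menten parameters (Km, kcat, kcat/Km) from rate-vs-substrate
  tables, with 95% confidence intervals.

Substrate loads are in mg ml^-1 of galactan; the monomer unit is counted
with the anhydrogalactose residue mass (162.14 g mol^-1), i.e. the mass of a
galactose unit inside a polymer chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import gcd

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ANHYDRO_GALACTOSE_MASS",
    "DigestSample",
    "DegradationProfile",
    "KineticsFit",
    "theoretical_max_reducing_ends",
    "compute_doh",
    "estimate_g_gt5",
    "endpoint_ratio",
    "fit_michaelis_menten",
    "degradation_profile",
]

#: Residue mass of an anhydrogalactose unit inside the polymer (g/mol).
ANHYDRO_GALACTOSE_MASS = 162.14
#: Free galactose mass, for users preferring the monomer convention (g/mol).
FREE_GALACTOSE_MASS = 180.16

GX_SPECIES = ("G1", "G2", "G3", "G4", "G5")


@dataclass
class DigestSample:
    """One digest measurement: analyte concentrations plus reducing ends."""

    sample_id: str
    enzyme_id: str
    substrate_load: float  # mg/ml
    analytes: dict[str, float]  # {G1..G5} -> mM
    reducing_ends: float  # mM

    def __post_init__(self) -> None:
        if self.substrate_load <= 0:
            raise ValueError("substrate_load must be positive")
        for species, conc in self.analytes.items():
            if species not in GX_SPECIES:
                raise ValueError(f"unknown analyte {species!r}; expected G1..G5")
            if conc < 0:
                raise ValueError(f"{species} concentration negative")
        if self.reducing_ends < 0:
            raise ValueError("reducing_ends negative")

    def analyte_sum(self) -> float:
        return float(sum(self.analytes.values()))


@dataclass
class DegradationProfile:
    """Per-sample DoH and G>5 estimates plus an enzyme endpoint ratio."""

    sample_ids: list[str]
    doh_percent: list[float]
    g_gt5_mM: list[float]
    endpoint_ratio: str | None = None


@dataclass
class KineticsFit:
    """Michaelis-Menten fit: Km (mg/ml), kcat (1/s), efficiency (ml/mg/s)."""

    km: float
    kcat: float
    vmax: float  # mM/s
    km_ci95: tuple[float, float]
    kcat_ci95: tuple[float, float]
    efficiency_ci95: tuple[float, float]
    n: int

    @property
    def efficiency(self) -> float:
        return self.kcat / self.km


def theoretical_max_reducing_ends(
    substrate_load: float, unit_mass: float = ANHYDRO_GALACTOSE_MASS
) -> float:
    """Reducing ends (mM) at full degradation of the load to galactose."""
    if substrate_load <= 0:
        raise ValueError("substrate_load must be positive")
    return substrate_load / unit_mass * 1000.0


def compute_doh(
    sample: DigestSample, unit_mass: float = ANHYDRO_GALACTOSE_MASS, slack: float = 0.05
) -> float:
    """Degree of hydrolysis in percent: reducing ends over the theoretical max.

    Values within ``slack`` (default 5%) above the maximum are attributed to
    assay noise and clipped to 100% with a warning; larger excesses raise.
    """
    max_re = theoretical_max_reducing_ends(sample.substrate_load, unit_mass)
    if sample.reducing_ends > (1.0 + slack) * max_re:
        raise ValueError(
            f"sample {sample.sample_id}: reducing ends {sample.reducing_ends:.3f} mM exceed "
            f"the theoretical maximum {max_re:.3f} mM by more than {slack:.0%}"
        )
    doh = 100.0 * sample.reducing_ends / max_re
    if doh > 100.0:
        warnings.warn(
            f"sample {sample.sample_id}: DoH {doh:.2f}% clipped to 100% (assay slack)",
            stacklevel=2,
        )
        doh = 100.0
    return doh


def estimate_g_gt5(sample: DigestSample) -> float:
    """Chains longer than G5, in reducing-end-equivalent mM.

    Every chain carries exactly one reducing end, so the difference between
    reducing ends and the quantified G1..G5 chains counts the longer chains.
    Small negative differences (quantification noise) clip to zero with a
    warning.
    """
    estimate = sample.reducing_ends - sample.analyte_sum()
    if estimate < 0:
        warnings.warn(
            f"sample {sample.sample_id}: G>5 estimate {estimate:.3f} mM negative; "
            "clipped to 0 (quantification noise)",
            stacklevel=2,
        )
        return 0.0
    return float(estimate)


def _best_integer_ratio(
    values: np.ndarray, max_denominator: int = 10, rel_tol: float = 0.05
) -> list[int]:
    """Small-integer ratio a:b:... fitting the values.

    Candidate units are fractions of the smallest nonzero value; among
    candidates whose worst relative error is within ``rel_tol`` of the best
    achievable (errors below tolerance count as ties), the smallest integer
    sum wins -- so quantification noise does not inflate the ratio.
    """
    vmin = values[values > 0].min()
    candidates: list[tuple[float, int, list[int]]] = []
    for k in range(1, max_denominator + 1):
        unit = vmin / k
        ints = np.maximum(np.rint(values / unit).astype(int), 0)
        if np.any((values > 0) & (ints == 0)):
            continue
        # refit the unit to the candidate integers (least squares)
        scale = float(np.dot(values, ints) / np.dot(ints, ints))
        err = float(np.max(np.abs(values - ints * scale) / np.where(values > 0, values, 1.0)))
        g = 0
        for v in ints:
            g = gcd(g, int(v))
        reduced = [int(v // g) for v in ints] if g > 0 else list(map(int, ints))
        candidates.append((err, sum(reduced), reduced))
    assert candidates
    best_err = min(c[0] for c in candidates)
    threshold = max(best_err, rel_tol)
    viable = [c for c in candidates if c[0] <= threshold]
    viable.sort(key=lambda c: (c[1], c[0]))
    return viable[0][2]


def endpoint_ratio(
    samples: list[DigestSample],
    species: tuple[str, ...] = ("G1", "G2", "G3"),
    max_denominator: int = 10,
) -> str:
    """Small-integer molar ratio of the requested species at the last sample.

    E.g. final concentrations (1.5, 1.0, 3.0) mM of (G1, G2, G3) give
    ``"3:2:6"``. Requires at least two nonzero species at the endpoint.
    """
    if not samples:
        raise ValueError("no samples provided")
    final = samples[-1]
    values = np.array([final.analytes.get(sp, 0.0) for sp in species], dtype=float)
    if np.all(values == 0):
        raise ValueError("all requested species are zero at the endpoint")
    if np.count_nonzero(values) < 2:
        raise ValueError("endpoint ratio requires at least two nonzero species")
    ints = _best_integer_ratio(values, max_denominator=max_denominator)
    return ":".join(str(v) for v in ints)


def _mm_model(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * s / (km + s)


def fit_michaelis_menten(
    s: np.ndarray,
    v: np.ndarray,
    enzyme_conc: float,
    enzyme_mw: float,
    ci_method: str = "linearized",
) -> KineticsFit:
    """Nonlinear least-squares Michaelis-Menten fit.

    Parameters
    ----------
    s : substrate concentrations, mg ml^-1 (>= 5 levels spanning Km).
    v : initial rates, mM s^-1.
    enzyme_conc : enzyme concentration, mg ml^-1.
    enzyme_mw : enzyme molar mass, g mol^-1 (converts Vmax to kcat).
    ci_method : ``"linearized"`` (covariance with t(n-2) quantiles, default)
        or ``"profile"`` (profile-likelihood via an F threshold).

    Returns Km (mg ml^-1), kcat (s^-1), efficiency kcat/Km (ml mg^-1 s^-1)
    and 95% confidence intervals for each.
    """
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    if s.shape != v.shape or s.ndim != 1:
        raise ValueError("s and v must be equal-length 1-D vectors")
    if len(s) < 5:
        raise ValueError("need at least 5 substrate levels")
    if np.any(s <= 0) or np.any(v <= 0):
        raise ValueError("substrate levels and rates must be positive")

    vmax0 = float(v.max()) * 1.2
    half = vmax0 / 2.4
    km0 = float(s[np.argmin(np.abs(v - half))])
    last_err: Exception | None = None
    popt = pcov = None
    for scale in (1.0, 0.3, 3.0, 10.0):
        try:
            popt, pcov = optimize.curve_fit(
                _mm_model, s, v, p0=(vmax0, max(km0 * scale, 1e-6)), maxfev=20000
            )
            break
        except RuntimeError as exc:
            last_err = exc
    if popt is None:
        raise RuntimeError(
            f"Michaelis-Menten fit did not converge after restarts: {last_err}"
        )
    vmax_hat, km_hat = (float(popt[0]), float(popt[1]))
    if vmax_hat <= 0 or km_hat <= 0:
        raise RuntimeError(
            f"non-physical parameter estimate (Vmax={vmax_hat:.3g}, Km={km_hat:.3g})"
        )
    if not np.all(np.isfinite(pcov)):
        raise RuntimeError(
            "singular covariance: the data do not constrain both Vmax and Km "
            "(e.g. rates are saturated over the whole substrate range)"
        )

    n = len(s)
    dof = n - 2
    tq = float(stats.t.ppf(0.975, dof))
    perr = np.sqrt(np.diag(pcov))

    e_molar = enzyme_conc / enzyme_mw  # mol/l
    to_kcat = 1e-3 / e_molar  # mM/s -> 1/s

    if ci_method == "linearized":
        vmax_hw, km_hw = tq * perr[0], tq * perr[1]
    elif ci_method == "profile":
        km_hw = _profile_halfwidth(s, v, vmax_hat, km_hat, dof)
        vmax_hw = tq * perr[0]
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    if km_hw > 10 * km_hat:
        raise RuntimeError(
            f"Km unidentifiable: 95% CI halfwidth {km_hw:.3g} dwarfs the estimate {km_hat:.3g}"
        )

    kcat_hat = vmax_hat * to_kcat
    kcat_hw = vmax_hw * to_kcat
    # efficiency CI by first-order (delta-method) error propagation
    eff = kcat_hat / km_hat
    rel = np.sqrt((kcat_hw / kcat_hat) ** 2 + (km_hw / km_hat) ** 2)
    eff_hw = eff * rel
    return KineticsFit(
        km=km_hat,
        kcat=kcat_hat,
        vmax=vmax_hat,
        km_ci95=(km_hat - km_hw, km_hat + km_hw),
        kcat_ci95=(kcat_hat - kcat_hw, kcat_hat + kcat_hw),
        efficiency_ci95=(eff - eff_hw, eff + eff_hw),
        n=n,
    )


def _profile_halfwidth(
    s: np.ndarray, v: np.ndarray, vmax_hat: float, km_hat: float, dof: int
) -> float:
    """Symmetrized profile-likelihood 95% halfwidth for Km."""
    rss0 = float(np.sum((v - _mm_model(s, vmax_hat, km_hat)) ** 2))
    threshold = rss0 * (1.0 + stats.f.ppf(0.95, 1, dof) / dof)

    def rss_at(km: float) -> float:
        num = np.sum(v * s / (km + s))
        den = np.sum((s / (km + s)) ** 2)
        vmax = num / den
        return float(np.sum((v - _mm_model(s, vmax, km)) ** 2))

    def edge(direction: int) -> float:
        lo, hi = km_hat, km_hat
        step = 0.1 * km_hat
        for _ in range(200):
            hi = hi + direction * step
            if hi <= 0:
                hi = km_hat * 1e-6
                break
            if rss_at(hi) > threshold:
                break
            step *= 1.5
        for _ in range(80):  # bisection
            mid = 0.5 * (lo + hi)
            if rss_at(mid) > threshold:
                hi = mid
            else:
                lo = mid
        return hi

    upper = edge(+1)
    lower = edge(-1)
    return 0.5 * (abs(upper - km_hat) + abs(km_hat - lower))


def degradation_profile(
    samples: list[DigestSample],
    ratio_species: tuple[str, ...] = ("G1", "G2", "G3"),
    unit_mass: float = ANHYDRO_GALACTOSE_MASS,
) -> DegradationProfile:
    """DoH and G>5 per sample plus the endpoint product ratio of a series."""
    doh = [compute_doh(s, unit_mass=unit_mass) for s in samples]
    ggt5 = [estimate_g_gt5(s) for s in samples]
    ratio = None
    try:
        ratio = endpoint_ratio(samples, species=ratio_species)
    except ValueError:
        pass
    return DegradationProfile(
        sample_ids=[s.sample_id for s in samples],
        doh_percent=doh,
        g_gt5_mM=ggt5,
        endpoint_ratio=ratio,
    )
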