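"""Equilibrium binding: Kd fitting for EMSA-style titrations.

The quantitation model is the protein-excess binding isotherm

    f([P]) = [P]^h / (Kd^h + [P]^h)

with the Hill coefficient h fixed at 1 by default (the complexes are
monomeric 1:1), valid because the labelled probe (~2 nM) is far below the
Kd range of interest (>= ~15 nM), so free protein ~ total protein.  An
exact ligand-depletion (quadratic) solution is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

#: The titration lane series used in the EMSA experiments, nM.
EMSA_LANE_SERIES = (0.0, 0.8, 1.6, 3.2, 6.25, 12.5, 25.0, 50.0, 100.0, 200.0)

DEFAULT_PROBE_NM = 2.0


class NoBindingError(ValueError):
    """Every titration point has zero fraction bound; Kd is undefined."""


class FitError(RuntimeError):
    """Nonlinear fit failed to converge."""


@dataclass(frozen=True)
class BindingCurve:
    """An already-quantified titration: protein concentration vs fraction bound."""

    protein_concentrations: tuple[float, ...]   # nM, strictly increasing, includes 0
    fraction_bound: tuple[float, ...]           # in [0, 1]
    probe_concentration: float = DEFAULT_PROBE_NM

    def __post_init__(self) -> None:
        conc = np.asarray(self.protein_concentrations, float)
        frac = np.asarray(self.fraction_bound, float)
        if conc.size != frac.size:
            raise ValueError("concentration and fraction lists differ in length")
        if conc.size < 4:
            raise ValueError(f"need >= 4 titration points, got {conc.size}")
        if conc[0] != 0.0:
            raise ValueError("titration must include a zero-protein point")
        if np.any(conc < 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be non-negative and strictly increasing")
        if np.any(frac < 0) or np.any(frac > 1):
            raise ValueError("fraction bound must lie in [0, 1]")
        if self.probe_concentration <= 0:
            raise ValueError("probe concentration must be positive")
        object.__setattr__(self, "protein_concentrations", tuple(float(c) for c in conc))
        object.__setattr__(self, "fraction_bound", tuple(float(f) for f in frac))


@dataclass(frozen=True)
class KdFit:
    kd: float                                   # nM
    hill: float
    rss: float
    ci95: tuple[float, float] | None = None     # bootstrap interval, nM

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("Kd must be positive")
        if self.ci95 is not None and not self.ci95[0] <= self.kd <= self.ci95[1]:
            raise ValueError("bootstrap interval must contain the point estimate")


def isotherm(conc, kd: float, hill: float = 1.0):
    """Protein-excess fraction bound, f = P^h / (Kd^h + P^h)."""
    conc = np.asarray(conc, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ph = np.power(conc, hill, where=conc > 0, out=np.zeros_like(conc))
    return ph / (kd ** hill + ph)


def isotherm_depletion(conc, kd: float, probe: float = DEFAULT_PROBE_NM):
    """Exact 1:1 fraction bound with ligand depletion (quadratic solution)."""
    p = np.asarray(conc, float)
    s = p + probe + kd
    return (s - np.sqrt(s ** 2 - 4.0 * p * probe)) / (2.0 * probe)


def _fit_once(conc: np.ndarray, frac: np.ndarray, fix_hill: bool,
              exact_depletion: bool, probe: float) -> tuple[float, float, float]:
    half = np.argmin(np.abs(frac - 0.5 * frac.max()))
    kd0 = max(float(conc[half]), 1e-3)
    try:
        if exact_depletion:
            popt, _ = curve_fit(
                lambda c, kd: isotherm_depletion(c, kd, probe),
                conc, frac, p0=[kd0], bounds=([1e-9], [np.inf]), maxfev=10000,
            )
            kd, hill = float(popt[0]), 1.0
        elif fix_hill:
            popt, _ = curve_fit(
                lambda c, kd: isotherm(c, kd, 1.0),
                conc, frac, p0=[kd0], bounds=([1e-9], [np.inf]), maxfev=10000,
            )
            kd, hill = float(popt[0]), 1.0
        else:
            popt, _ = curve_fit(
                isotherm, conc, frac, p0=[kd0, 1.0],
                bounds=([1e-9, 0.1], [np.inf, 4.0]), maxfev=10000,
            )
            kd, hill = float(popt[0]), float(popt[1])
    except RuntimeError as exc:
        raise FitError(f"isotherm fit did not converge (kd0={kd0:.3g} nM): {exc}") from exc
    model = isotherm_depletion(conc, kd, probe) if exact_depletion else isotherm(conc, kd, hill)
    rss = float(((frac - model) ** 2).sum())
    return kd, hill, rss


def fit_kd(
    curve: BindingCurve,
    fix_hill: bool = True,
    exact_depletion: bool = False,
    bootstrap: int = 0,
    seed: int = 0,
) -> KdFit:
    """Fit the dissociation constant from a titration curve.

    Nonlinear least squares with Kd > 0, initialized at the concentration
    nearest half-maximal binding.  ``bootstrap`` > 0 adds a seeded residual
    bootstrap percentile 95% interval: the titration design is fixed, so
    centred, dof-corrected residuals (inflated by sqrt(n / (n - 2)) for the
    fitted parameter and the centring) are resampled onto the fitted curve
    and the fit repeated.  The interval is widened, if necessary, to contain
    the point estimate.
    """
    conc = np.asarray(curve.protein_concentrations)
    frac = np.asarray(curve.fraction_bound)
    if not np.any(frac > 0):
        raise NoBindingError("all fractions bound are zero: no binding detected")
    kd, hill, rss = _fit_once(conc, frac, fix_hill, exact_depletion,
                              curve.probe_concentration)
    ci = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        fitted = (isotherm_depletion(conc, kd, curve.probe_concentration)
                  if exact_depletion else isotherm(conc, kd, hill))
        resid = frac - fitted
        resid = (resid - resid.mean()) * np.sqrt(len(conc) / (len(conc) - 2))
        estimates = []
        for _ in range(bootstrap):
            f_b = np.clip(fitted + rng.choice(resid, size=len(resid)), 0.0, 1.0)
            if not np.any(f_b > 0):
                continue
            try:
                kd_b, _, _ = _fit_once(conc, f_b, fix_hill, exact_depletion,
                                       curve.probe_concentration)
            except FitError:
                continue
            estimates.append(kd_b)
        if estimates:
            lo, hi = np.percentile(estimates, [2.5, 97.5])
            ci = (min(float(lo), kd), max(float(hi), kd))
    return KdFit(kd=kd, hill=hill, rss=rss, ci95=ci)


def simulate_titration(
    kd: float,
    concentrations=EMSA_LANE_SERIES,
    noise_sd: float = 0.0,
    seed: int = 0,
    probe_concentration: float = DEFAULT_PROBE_NM,
) -> BindingCurve:
    """Synthetic titration: isotherm values plus Gaussian noise clipped to [0, 1].

    Deterministic under a fixed seed.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    conc = np.asarray(concentrations, float)
    frac = isotherm(conc, kd)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frac = frac + rng.normal(0.0, noise_sd, size=conc.size)
    frac = np.clip(frac, 0.0, 1.0)
    return BindingCurve(tuple(conc), tuple(frac), probe_concentration)


def read_curve_tsv(path: str | Path) -> BindingCurve:
    """Read a titration TSV with columns ``conc_nM`` and ``fraction_bound``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for col in ("conc_nM", "fraction_bound"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return BindingCurve(tuple(df["conc_nM"].astype(float)),
                        tuple(df["fraction_bound"].astype(float)))


def write_curve_tsv(curve: BindingCurve, path: str | Path) -> None:
    lines = ["conc_nM\tfraction_bound"]
    for c, f in zip(curve.protein_concentrations, curve.fraction_bound):
        lines.append(f"{c:g}\t{f:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
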