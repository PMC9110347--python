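"""Visual-pigment templates, spectral filtering, and mixture decomposition.

Pigment absorbance curves are modelled with the standard Govardovskii-type
A1 (retinal chromophore) nomogram, parameterized solely by the wavelength
of maximum absorbance λ_max and comprising the main α-band plus the
secondary short-wavelength β-band, normalized to unit absorbance at
λ_max. Microspectrophotometric records that contain more than one pigment
(opsin co-expression) are decomposed with the response model

    R(λ) = [ Σ_i k_i · A_i^p(λ) ]^(1/p)

where A_i is the template of pigment i, the k_i ≥ 0 are coupling
constants, and the exponent p > 0 keeps the fitted absorbance function
differentiable at the origin. The k_i and p are found by Nelder–Mead
simplex minimization of the sum of squared residuals (SS), with
positivity enforced through a log-parameterization and multiple starts;
competing pigment combinations are ranked by their best SS.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datatypes import PigmentTemplate, Spectrum

__all__ = [
    "MixtureModelFit",
    "LambdaMaxEstimate",
    "template_absorbance",
    "fourier_filter",
    "estimate_lambda_max",
    "half_max_bandwidth_wavenumber",
    "mixture_response",
    "fit_mixture",
]

A1_LAMBDA_MAX_RANGE = (330.0, 620.0)


def _govardovskii_a1(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """Unnormalized A1 nomogram (α-band + β-band) at the given λ_max."""
    lam = np.asarray(wavelengths, dtype=float)
    x = lambda_max / lam
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    beta_max = 189.0 + 0.315 * lambda_max
    beta_band = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((lam - beta_max) / beta_band) ** 2))
    return alpha + beta


def template_absorbance(lambda_max: float, grid) -> PigmentTemplate:
    """A1 visual-pigment template on a wavelength grid, unit peak at λ_max.

    Valid for 330 nm ≤ λ_max ≤ 620 nm (the A1 nomogram's range). The
    curve is normalized by its value at λ_max so the peak equals 1 within
    grid resolution.
    """
    lo, hi = A1_LAMBDA_MAX_RANGE
    if not lo <= lambda_max <= hi:
        raise ValueError(
            f"lambda_max {lambda_max} nm outside A1 template validity "
            f"range [{lo}, {hi}] nm"
        )
    grid = np.asarray(grid, dtype=float).ravel()
    values = _govardovskii_a1(grid, lambda_max)
    peak = float(_govardovskii_a1(np.asarray([lambda_max]), lambda_max)[0])
    return PigmentTemplate(lambda_max=float(lambda_max), wavelengths=grid,
                           values=values / peak)


def fourier_filter(spectrum: Spectrum, cutoff_period: float = 40.0) -> Spectrum:
    """Low-pass Fourier filter: zero all components of period < cutoff.

    Operates on a uniform wavelength grid; the DC component (spectrum
    mean) is preserved exactly. ``cutoff_period`` is in nm and must exceed
    twice the grid step (the Nyquist period).
    """
    if not spectrum.is_uniform:
        raise ValueError("Fourier filtering requires a uniform wavelength grid")
    step = spectrum.step
    if cutoff_period <= 2.0 * step:
        raise ValueError(
            f"cutoff period {cutoff_period} nm must exceed twice the grid "
            f"step ({2 * step} nm)"
        )
    y = spectrum.absorbance
    coeffs = np.fft.rfft(y)
    freqs = np.fft.rfftfreq(y.size, d=step)  # cycles per nm
    coeffs[freqs > 1.0 / cutoff_period] = 0.0
    filtered = np.fft.irfft(coeffs, n=y.size)
    meta = dict(spectrum.meta)
    meta["fourier_cutoff_nm"] = cutoff_period
    return Spectrum(spectrum.wavelengths.copy(), filtered, meta)


@dataclass(frozen=True)
class LambdaMaxEstimate:
    lambda_max_nm: float
    scale: float
    ss: float


def estimate_lambda_max(spectrum: Spectrum,
                        search_range: tuple[float, float] = (350.0, 620.0)
                        ) -> LambdaMaxEstimate:
    """Estimate a single pigment's λ_max by template matching.

    A single A1 template with a least-squares-fitted scale is scanned over
    a 1 nm grid across ``search_range`` (clamped to template validity) and
    the best candidate refined by bounded scalar minimization. Returns the
    λ_max, the fitted scale, and the residual sum of squares.
    """
    y = spectrum.absorbance
    if not np.any(np.abs(y - y[0]) > 1e-12) or float(np.ptp(y)) <= 0:
        raise ValueError("spectrum is flat; lambda_max is undefined")
    lo = max(search_range[0], A1_LAMBDA_MAX_RANGE[0])
    hi = min(search_range[1], A1_LAMBDA_MAX_RANGE[1])
    if hi <= lo:
        raise ValueError("empty search range after clamping to template validity")

    def ss_at(lmax: float) -> float:
        t = template_absorbance(lmax, spectrum.wavelengths).values
        denom = float(t @ t)
        scale = float(t @ y) / denom if denom > 0 else 0.0
        r = y - scale * t
        return float(r @ r)

    coarse = np.arange(lo, hi + 0.5, 1.0)
    best = float(coarse[int(np.argmin([ss_at(l) for l in coarse]))])
    res = optimize.minimize_scalar(
        ss_at, bounds=(max(lo, best - 2.0), min(hi, best + 2.0)),
        method="bounded", options={"xatol": 1e-4},
    )
    lmax = float(res.x)
    t = template_absorbance(lmax, spectrum.wavelengths).values
    scale = float(t @ y) / float(t @ t)
    return LambdaMaxEstimate(lmax, scale, float(res.fun))


def _as_arrays(spectrum_or_template) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(spectrum_or_template, PigmentTemplate):
        return spectrum_or_template.wavelengths, spectrum_or_template.values
    return spectrum_or_template.wavelengths, spectrum_or_template.absorbance


def half_max_bandwidth_wavenumber(spectrum_or_template) -> float:
    """Full bandwidth at half maximum of the α-band, in wavenumbers (cm⁻¹).

    Wavelengths are converted to wavenumber ν = 10⁷/λ(nm); the two
    half-maximum crossings flanking the absorbance peak are located by
    linear interpolation in ν and their separation ν_blue − ν_red
    returned (positive). Raises if a flank never crosses half maximum
    within the grid, naming the missing flank.
    """
    lam, y = _as_arrays(spectrum_or_template)
    nu = 1e7 / lam  # descending in ν as λ ascends
    i_peak = int(np.argmax(y))
    half = float(y[i_peak]) / 2.0
    if y[i_peak] <= 0:
        raise ValueError("spectrum has no positive maximum")

    def crossing(idx_from: int, direction: int) -> float:
        i = idx_from
        while 0 <= i + direction < y.size:
            j = i + direction
            if y[j] < half <= y[i]:
                f = (half - y[i]) / (y[j] - y[i])
                return float(nu[i] + f * (nu[j] - nu[i]))
            i = j
        flank = "red" if direction > 0 else "blue"
        raise ValueError(
            f"half maximum not bracketed on the {flank} flank within the grid"
        )

    nu_red = crossing(i_peak, +1)   # longer λ, smaller ν
    nu_blue = crossing(i_peak, -1)  # shorter λ, larger ν
    return nu_blue - nu_red


def mixture_response(k, p: float, pigment_set, grid) -> Spectrum:
    """Evaluate the mixture response R = [Σ_i k_i A_i^p]^(1/p) on a grid."""
    k = np.asarray(k, dtype=float).ravel()
    lmaxes = np.asarray(pigment_set, dtype=float).ravel()
    if k.size != lmaxes.size:
        raise ValueError("k and pigment_set must have the same length")
    if k.size == 0:
        raise ValueError("at least one pigment is required")
    if np.any(k < 0):
        raise ValueError("coupling constants must be non-negative")
    if not p > 0:
        raise ValueError("exponent p must be positive")
    grid = np.asarray(grid, dtype=float).ravel()
    a = np.stack([template_absorbance(l, grid).values for l in lmaxes])
    r = np.power(k @ np.power(a, p), 1.0 / p)
    return Spectrum(grid, r, {"k": k.tolist(), "p": float(p),
                              "pigments": lmaxes.tolist()})


@dataclass
class MixtureModelFit:
    """Best-fit mixture parameters for one candidate pigment set."""

    pigment_set: tuple[float, ...]
    k: np.ndarray
    p: float
    ss: float
    fitted_curve: Spectrum
    converged: bool

    def as_dict(self) -> dict:
        return {
            "pigments_nm": list(self.pigment_set),
            "k": [float(v) for v in self.k],
            "p": float(self.p),
            "ss": float(self.ss),
            "converged": bool(self.converged),
        }


def _fit_one_set(y: np.ndarray, grid: np.ndarray, lmaxes: np.ndarray,
                 p_starts, maxiter: int, fatol: float) -> MixtureModelFit:
    a = np.stack([template_absorbance(l, grid).values for l in lmaxes])
    m = lmaxes.size
    peak_idx = np.array([int(np.argmin(np.abs(grid - l))) for l in lmaxes])

    def ss_of(theta: np.ndarray) -> float:
        k = np.exp(theta[:m])
        p = np.exp(theta[m])
        if p > 60.0:  # numerically meaningless region
            return 1e12
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            r = np.power(k @ np.power(a, p), 1.0 / p)
        if not np.all(np.isfinite(r)):
            return 1e12
        d = r - y
        return float(d @ d)

    best_theta, best_ss, best_ok = None, np.inf, False
    for p0 in p_starts:
        # peak-matching heuristic: R(λ_max,i) ≈ k_i^(1/p) when pigment i
        # dominates its own peak, so k0_i = y(λ_max,i)^p0
        k0 = np.maximum(y[peak_idx], 1e-3) ** p0
        theta0 = np.concatenate([np.log(k0), [np.log(p0)]])
        res = optimize.minimize(
            ss_of, theta0, method="Nelder-Mead",
            options={"maxiter": maxiter, "fatol": fatol, "xatol": 1e-10},
        )
        # one restart from the incumbent to escape simplex collapse
        res2 = optimize.minimize(
            ss_of, res.x, method="Nelder-Mead",
            options={"maxiter": maxiter, "fatol": fatol, "xatol": 1e-10},
        )
        for r in (res, res2):
            if r.fun < best_ss:
                best_theta, best_ss, best_ok = r.x, float(r.fun), bool(r.success)
    k = np.exp(best_theta[:m])
    p = float(np.exp(best_theta[m]))
    fitted = mixture_response(k, p, lmaxes, grid)
    resid = fitted.absorbance - y
    return MixtureModelFit(
        pigment_set=tuple(float(l) for l in lmaxes),
        k=k, p=p, ss=float(resid @ resid), fitted_curve=fitted,
        converged=best_ok,
    )


def fit_mixture(spectrum: Spectrum, candidate_sets,
                p_starts=(1.0, 2.0, 4.0), maxiter: int = 5000,
                fatol: float = 1e-12) -> list[MixtureModelFit]:
    """Fit each candidate pigment combination and rank by least SS.

    Each candidate set is a sequence of λ_max values. For each set the
    coupling constants and exponent are optimized by Nelder–Mead simplex
    over log-parameters (three starts with p₀ ∈ {1, 2, 4} by default, k₀
    from peak matching, plus a restart from each incumbent). Fits are
    returned sorted by ascending SS; non-convergent fits are flagged but
    still reported.
    """
    if len(candidate_sets) == 0:
        raise ValueError("candidate_sets must not be empty")
    sets = [np.asarray(s, dtype=float).ravel() for s in candidate_sets]
    for s in sets:
        if s.size == 0:
            raise ValueError("every candidate set must contain >= 1 pigment")
    y = spectrum.absorbance
    grid = spectrum.wavelengths
    fits = [_fit_one_set(y, grid, s, p_starts, maxiter, fatol) for s in sets]
    return sorted(fits, key=lambda f: f.ss)
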