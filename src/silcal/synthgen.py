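"""Synthetic NIR spectra, reference values and ruminal degradation curves.

The generator emulates the structure of dried-and-ground forage spectra
recorded as log(1/R) over 902-1680 nm: a handful of broad, overlapping
absorption bands per chemical component, per-sample multiplicative scatter
(gain and additive offset), a mild linear baseline drift and additive
instrument noise.  Reference property values (% DM) are exact linear
functions of the latent component concentrations, so with noise and scatter
switched off every property is exactly recoverable by a linear calibration
-- the ground truth every downstream stage is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_io import ReferenceTable, SpectraSet

__all__ = [
    "ComponentLibrary",
    "SimulationRecipe",
    "KineticGroundTruth",
    "gen_pure_components",
    "gen_spectra_dataset",
    "gen_degradation_curves",
    "default_library",
    "default_recipe",
]

WL_MIN = 902.0
WL_MAX = 1680.0


@dataclass(frozen=True)
class ComponentLibrary:
    """Pure-component absorbance profiles on a common wavelength grid.

    Each profile is a sum of Gaussian bands (center nm, width nm, height
    a.u.), hence smooth, non-negative and strongly collinear across
    components -- the regime NIR calibrations live in.
    """

    wavelengths: np.ndarray  # (n_channels,), nm, strictly increasing
    pure_spectra: np.ndarray  # (n_components, n_channels), a.u., >= 0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ps = np.atleast_2d(np.asarray(self.pure_spectra, dtype=float))
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength axis must be 1-D with >= 2 points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if ps.shape[0] < 1:
            raise ValueError("need at least one component profile")
        if ps.shape[1] != wl.size:
            raise ValueError("profiles and wavelength axis disagree in length")
        if np.any(ps < 0):
            raise ValueError("pure-component profiles must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "pure_spectra", ps)

    @property
    def n_components(self) -> int:
        return self.pure_spectra.shape[0]

    @property
    def n_channels(self) -> int:
        return self.wavelengths.size


def gen_pure_components(
    n_components: int,
    n_channels: int = 256,
    seed: int = 0,
    *,
    wl_min: float = WL_MIN,
    wl_max: float = WL_MAX,
    bands_per_component: tuple[int, int] = (3, 6),
) -> ComponentLibrary:
    """Draw a library of Gaussian-band pure spectra.

    Each component gets 3-6 bands with centers inside the wavelength range,
    widths of 25-120 nm and heights of 0.2-1.0 a.u.  Deterministic for a
    fixed seed.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_channels < 8:
        raise ValueError("n_channels must be >= 8")
    lo, hi = bands_per_component
    rng = np.random.default_rng(seed)
    wl = np.linspace(wl_min, wl_max, n_channels)
    profiles = np.zeros((n_components, n_channels))
    for i in range(n_components):
        n_bands = int(rng.integers(lo, hi + 1))
        centers = rng.uniform(wl_min, wl_max, n_bands)
        widths = rng.uniform(25.0, 120.0, n_bands)
        heights = rng.uniform(0.2, 1.0, n_bands)
        for c, w, h in zip(centers, widths, heights):
            profiles[i] += h * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return ComponentLibrary(wavelengths=wl, pure_spectra=profiles)


@dataclass(frozen=True)
class SimulationRecipe:
    """Everything needed to turn a component library into a dataset.

    ``property_loadings`` is the (n_properties, n_components) non-negative
    linear map from component concentrations to property values (% DM); with
    concentration ranges [m_k, M_k] the attainable property range is
    [L @ m, L @ M], so configured ranges are respected by construction.
    """

    n_samples: int
    concentration_ranges: np.ndarray  # (n_components, 2) min/max
    property_loadings: np.ndarray  # (n_properties, n_components), >= 0
    property_names: tuple[str, ...]
    noise_sd: float = 0.002  # additive absorbance noise, a.u.
    gain_range: tuple[float, float] = (0.8, 1.2)  # multiplicative scatter
    offset_range: tuple[float, float] = (-0.05, 0.05)  # additive scatter, a.u.
    baseline_slope_range: tuple[float, float] = (-2e-4, 2e-4)  # a.u./channel
    seed: int = 0

    def __post_init__(self) -> None:
        cr = np.atleast_2d(np.asarray(self.concentration_ranges, dtype=float))
        L = np.atleast_2d(np.asarray(self.property_loadings, dtype=float))
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if cr.shape[1] != 2 or not np.all(np.isfinite(cr)):
            raise ValueError("concentration_ranges must be a finite (k, 2) array")
        if np.any(cr[:, 0] > cr[:, 1]):
            raise ValueError("concentration ranges need min <= max")
        if L.shape[1] != cr.shape[0]:
            raise ValueError(
                "property_loadings columns must match the number of components"
            )
        if len(self.property_names) != L.shape[0]:
            raise ValueError("one property name per loading row required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "concentration_ranges", cr)
        object.__setattr__(self, "property_loadings", L)
        object.__setattr__(self, "property_names", tuple(self.property_names))

    def property_ranges(self) -> np.ndarray:
        """Attainable (n_properties, 2) min/max given the loadings."""
        L = self.property_loadings
        lo = np.where(L >= 0, self.concentration_ranges[:, 0], self.concentration_ranges[:, 1])
        hi = np.where(L >= 0, self.concentration_ranges[:, 1], self.concentration_ranges[:, 0])
        return np.column_stack([(L * lo).sum(axis=1), (L * hi).sum(axis=1)])


def gen_spectra_dataset(
    library: ComponentLibrary, recipe: SimulationRecipe
) -> tuple[SpectraSet, ReferenceTable]:
    """Simulate a spectra matrix and its aligned reference table.

    spectra = gain * (concentrations @ pure_spectra) + offset
              + slope * channel_index + noise
    properties = concentrations @ loadings.T
    """
    if recipe.concentration_ranges.shape[0] != library.n_components:
        raise ValueError(
            "recipe is dimensioned for "
            f"{recipe.concentration_ranges.shape[0]} components but the "
            f"library has {library.n_components}"
        )
    rng = np.random.default_rng(recipe.seed)
    n, k = recipe.n_samples, library.n_components
    lo = recipe.concentration_ranges[:, 0]
    hi = recipe.concentration_ranges[:, 1]
    conc = lo + (hi - lo) * rng.random((n, k))
    clean = conc @ library.pure_spectra
    gain = rng.uniform(*recipe.gain_range, size=n)
    offset = rng.uniform(*recipe.offset_range, size=n)
    slope = rng.uniform(*recipe.baseline_slope_range, size=n)
    channels = np.arange(library.n_channels, dtype=float)
    spectra = (
        gain[:, None] * clean
        + offset[:, None]
        + slope[:, None] * channels[None, :]
    )
    if recipe.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, recipe.noise_sd, size=spectra.shape)
    props = conc @ recipe.property_loadings.T
    ids = [f"S{i + 1:03d}" for i in range(n)]
    sset = SpectraSet(sample_ids=ids, wavelengths=library.wavelengths, absorbance=spectra)
    refs = ReferenceTable.from_arrays(ids, recipe.property_names, props)
    return sset, refs


# -- default study conditions -------------------------------------------------
#
# Four latent components: component 0 is a constant-concentration matrix
# background that carries each property's floor; components 1-3 vary in
# [0, 1], so noiseless spectra live in a 3-dimensional centered subspace
# and every property is exactly recovered by a 3-latent-variable PLS.
# Loadings are chosen so the attainable property ranges match the span
# typically seen in Brazilian corn-silage surveys: CP 5.00-9.06,
# NDF 34.15-57.81, starch 11.00-40.53, DM 20.43-41.61, EE 1.26-3.76 (% DM).

_DEFAULT_PROPERTIES = ("CP", "NDF", "starch", "DM", "EE")
_DEFAULT_LOADINGS = np.array(
    [
        # comp0   comp1   comp2   comp3
        [5.00, 2.80, 0.90, 0.36],  # CP    -> [5.00, 9.06]
        [34.15, 3.00, 14.00, 6.66],  # NDF   -> [34.15, 57.81]
        [11.00, 5.00, 12.00, 12.53],  # starch-> [11.00, 40.53]
        [20.43, 7.00, 6.18, 8.00],  # DM    -> [20.43, 41.61]
        [1.26, 0.90, 0.80, 0.80],  # EE    -> [1.26, 3.76]
    ]
)
_DEFAULT_CONC_RANGES = np.array(
    [[1.0, 1.0], [0.0, 1.0], [0.0, 1.0], [0.0, 1.0]]
)


def default_library(seed: int = 0, n_channels: int = 256) -> ComponentLibrary:
    """Four-component library matching :func:`default_recipe`."""
    return gen_pure_components(4, n_channels, seed=seed)


def default_recipe(n_samples: int = 94, seed: int = 0, **overrides) -> SimulationRecipe:
    """The default study conditions (94 samples, 256 channels, 5 properties)."""
    kwargs = dict(
        n_samples=n_samples,
        concentration_ranges=_DEFAULT_CONC_RANGES,
        property_loadings=_DEFAULT_LOADINGS,
        property_names=_DEFAULT_PROPERTIES,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationRecipe(**kwargs)


# -- degradation curves -------------------------------------------------------

STANDARD_TIMES = (0.0, 3.0, 6.0, 12.0, 24.0, 48.0, 72.0, 96.0)


@dataclass(frozen=True)
class KineticGroundTruth:
    """True parameters behind a simulated in situ degradation curve.

    ``first_order`` uses (a, b, kd): degraded(t) = a + b(1 - e^(-kd t)).
    ``gamma2`` uses (b, lam, I): residue(t) = b(1 + lam t)e^(-lam t) + I.
    """

    model_kind: str  # "first_order" | "gamma2"
    params: tuple[float, ...]
    times: tuple[float, ...] = STANDARD_TIMES
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 1 or np.any(t < 0) or 0.0 not in t:
            raise ValueError("times must be non-negative and include 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.model_kind == "first_order":
            a, b, kd = self.params
            if a < 0 or b < 0 or a + b > 100 or kd <= 0:
                raise ValueError("need a >= 0, b >= 0, a + b <= 100, kd > 0")
        elif self.model_kind == "gamma2":
            b, lam, i_frac = self.params
            if b < 0 or i_frac < 0 or b + i_frac > 100 or lam <= 0:
                raise ValueError("need b >= 0, I >= 0, b + I <= 100, lambda > 0")
        else:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")


def gen_degradation_curves(truth: KineticGroundTruth, seed: int = 0, n_curves: int = 1):
    """Simulate in situ curves from a kinetic ground truth.

    Returns a list of :class:`~silcal.kinetics.DegradationCurve`.  Noiseless
    curves equal the model closed form at every time; with ``noise_sd > 0``
    i.i.d. Gaussian noise (in % units) is added.  The noise path is not
    touched at all when ``noise_sd == 0``, so the seed is then irrelevant.
    """
    from .kinetics import DegradationCurve, first_order_degraded, gamma2_residue

    t = np.asarray(truth.times, dtype=float)
    if truth.model_kind == "first_order":
        clean = first_order_degraded(t, *truth.params)
        kind = "degraded"
    else:
        clean = gamma2_residue(t, *truth.params)
        kind = "residue"
    curves = []
    rng = np.random.default_rng(seed) if truth.noise_sd > 0 else None
    for _ in range(n_curves):
        vals = clean.copy()
        if rng is not None:
            vals = vals + rng.normal(0.0, truth.noise_sd, size=vals.shape)
        curves.append(DegradationCurve(times=t, values=vals, kind=kind))
    return curves
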