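"""Seeded generator of Raman-like synthetic datasets.

Two families of class recipes are provided, emulating the qualitative
structure of the two spectral domains the pipeline bridges:

* *mineral-like* classes: one or two narrow lines (FWHM 5-15 cm^-1), each
  class at distinct centers within 600-1100 cm^-1 — the source domain a
  feature extractor is pretrained on;
* *ivory-like* classes: broad overlapping bands (FWHM 25-60 cm^-1) at the
  dentine positions 960 (phosphate), 1070 (carbonate), 1240/1270 (amide III),
  1450 (CH2) and 1665 cm^-1 (amide I — deliberately outside the default
  600-1640 cm^-1 trim window), with the two classes differing *only* in the
  960 cm^-1 band (a center shift plus an amplitude change), mirroring the
  band that carries the inter-species signal in real dentine spectra.

Each spectrum is a sum of Gaussian/Lorentzian peaks with per-spectrum jitter
on peak centers and amplitudes, a low-order polynomial baseline, and additive
Gaussian noise. This is a minimal statistical model adequate for exercising
classifiers — not a physical Raman simulator (no fluorescence, cross-sections
or detector response).

Determinism: each spectrum draws from its own ``SeedSequence([seed,
class_index, replicate])`` stream, so datasets are byte-identical for a given
(recipes, grid, seed) and independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .spectra_io import LabeledDataset, Spectrum

__all__ = [
    "PeakSpec",
    "ClassRecipe",
    "render_spectrum",
    "make_presets",
    "mineral_recipes",
    "ivory_recipes",
    "generate_dataset",
    "make_ivory_standin",
    "default_grid",
]

# grid emulating the acquisition range of the dentine spectra (593-1704 cm^-1)
def default_grid(step: float = 1.0) -> np.ndarray:
    return np.arange(593.0, 1704.0 + step / 2, step)


@dataclass(frozen=True)
class PeakSpec:
    """One spectral line: center (cm^-1), amplitude, FWHM (cm^-1), shape."""

    center: float
    amplitude: float
    fwhm: float
    shape: str = "gaussian"

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be positive, got {self.fwhm}")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def profile(self, w: np.ndarray, center: float, amplitude: float) -> np.ndarray:
        if self.shape == "gaussian":
            # FWHM = 2*sqrt(2 ln 2) * sd
            sd = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            return amplitude * np.exp(-0.5 * ((w - center) / sd) ** 2)
        hwhm = self.fwhm / 2.0
        return amplitude * hwhm**2 / ((w - center) ** 2 + hwhm**2)


@dataclass(frozen=True)
class ClassRecipe:
    """Generative description of one spectral class.

    ``baseline_coeffs`` are polynomial coefficients (highest degree first,
    degree <= 3) in the scaled coordinate u = (w - 1150) / 550, keeping
    magnitudes O(1) across the grid.
    """

    name: str
    peaks: tuple[PeakSpec, ...]
    baseline_coeffs: tuple[float, ...] = (0.0,)
    noise_sd: float = 0.02
    center_jitter_sd: float = 1.0
    amplitude_jitter_rel_sd: float = 0.05

    def __post_init__(self):
        object.__setattr__(self, "peaks", tuple(self.peaks))
        if not self.peaks:
            raise ValueError(f"recipe {self.name!r} needs at least one peak")
        if len(self.baseline_coeffs) > 4:
            raise ValueError("baseline degree is capped at 3")
        if self.noise_sd < 0 or self.center_jitter_sd < 0 or self.amplitude_jitter_rel_sd < 0:
            raise ValueError("noise/jitter magnitudes must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassRecipe":
        d = dict(d)
        d["peaks"] = tuple(PeakSpec(**p) for p in d["peaks"])
        d["baseline_coeffs"] = tuple(d.get("baseline_coeffs", (0.0,)))
        return cls(**d)


def render_spectrum(recipe: ClassRecipe, grid: np.ndarray,
                    rng: np.random.Generator, spectrum_id: str = "") -> Spectrum:
    """Draw one spectrum from a recipe: jittered peaks + baseline + noise."""
    grid = np.asarray(grid, dtype=float)
    y = np.polyval(recipe.baseline_coeffs, (grid - 1150.0) / 550.0)
    y = np.broadcast_to(y, grid.shape).astype(float).copy()
    for peak in recipe.peaks:
        center = peak.center + rng.normal(0.0, recipe.center_jitter_sd) \
            if recipe.center_jitter_sd > 0 else peak.center
        amp = peak.amplitude * max(1e-6, 1.0 + rng.normal(0.0, recipe.amplitude_jitter_rel_sd)) \
            if recipe.amplitude_jitter_rel_sd > 0 else peak.amplitude
        y += peak.profile(grid, center, amp)
    if recipe.noise_sd > 0:
        y += rng.normal(0.0, recipe.noise_sd, grid.shape)
    meta = {"id": spectrum_id or recipe.name, "class_recipe": recipe.name}
    return Spectrum(grid, y, meta)


# ---------------------------------------------------------------------------
# presets

_MINERAL_CENTERS = [
    ("narrowline_620", [(620.0, 1.0, 8.0, "gaussian")]),
    ("narrowline_665", [(665.0, 0.9, 6.0, "lorentzian")]),
    ("narrowline_710", [(710.0, 1.1, 10.0, "gaussian")]),
    ("narrowline_755", [(755.0, 1.0, 7.0, "gaussian"), (1060.0, 0.4, 9.0, "gaussian")]),
    ("narrowline_800", [(800.0, 0.8, 12.0, "lorentzian")]),
    ("narrowline_845", [(845.0, 1.2, 5.0, "gaussian")]),
    ("narrowline_890", [(890.0, 1.0, 9.0, "gaussian"), (640.0, 0.5, 6.0, "lorentzian")]),
    ("narrowline_935", [(935.0, 0.9, 14.0, "gaussian")]),
    ("narrowline_980", [(980.0, 1.0, 8.0, "lorentzian")]),
    ("narrowline_1025", [(1025.0, 1.1, 6.0, "gaussian")]),
    ("narrowline_1070", [(1070.0, 1.0, 11.0, "gaussian"), (820.0, 0.3, 7.0, "gaussian")]),
    ("narrowline_1095", [(1095.0, 0.9, 15.0, "lorentzian")]),
]

# bands shared by the two ivory-like classes (all but the 960 cm^-1 entry)
_IVORY_COMMON = [
    PeakSpec(1070.0, 0.35, 35.0),
    PeakSpec(1240.0, 0.25, 40.0),
    PeakSpec(1270.0, 0.25, 40.0),
    PeakSpec(1450.0, 0.30, 45.0),
    PeakSpec(1665.0, 0.40, 50.0),  # amide I, outside the default trim window
]
_IVORY_BASELINE = (0.02, -0.03, 0.05, 0.10)


def mineral_recipes(noise_sd: float = 0.02) -> dict[str, ClassRecipe]:
    """Twelve narrow-band single/double-line source-domain classes."""
    out = {}
    for name, peaks in _MINERAL_CENTERS:
        out[name] = ClassRecipe(
            name=name,
            peaks=tuple(PeakSpec(*p[:3], shape=p[3]) for p in peaks),
            baseline_coeffs=(0.01, 0.02, 0.05),
            noise_sd=noise_sd,
            center_jitter_sd=0.5,
            amplitude_jitter_rel_sd=0.05,
        )
    return out


def ivory_recipes(noise_sd: float = 0.02) -> dict[str, ClassRecipe]:
    """Two broad-band classes differing only in the 960 cm^-1 phosphate band.

    The discriminating band differs by a 6 cm^-1 center shift (960 vs 966)
    and a 5% amplitude change. The shift is deliberately the dominant cue:
    the phosphate band is each spectrum's global maximum, so per-spectrum
    min-max normalisation maps its height to 1 for both classes — an
    amplitude-only difference would not survive the default preprocessing,
    whereas a center shift stays localised at 960 cm^-1.
    """
    def recipe(name: str, phosphate: PeakSpec) -> ClassRecipe:
        return ClassRecipe(
            name=name,
            peaks=(phosphate, *_IVORY_COMMON),
            baseline_coeffs=_IVORY_BASELINE,
            noise_sd=noise_sd,
            center_jitter_sd=1.0,
            amplitude_jitter_rel_sd=0.05,
        )
    return {
        "mammoth_like": recipe("mammoth_like", PeakSpec(960.0, 1.0, 30.0)),
        "elephant_like": recipe("elephant_like", PeakSpec(966.0, 0.95, 30.0)),
    }


def make_presets(noise_sd: float = 0.02) -> dict[str, ClassRecipe]:
    """All named recipes: >= 10 mineral-like plus the two ivory-like classes."""
    out = mineral_recipes(noise_sd)
    out.update(ivory_recipes(noise_sd))
    return out


# ---------------------------------------------------------------------------
# dataset generation

def generate_dataset(recipes: list[ClassRecipe] | dict[str, ClassRecipe],
                     n_per_class: int | dict[str, int],
                     grid: np.ndarray | None = None,
                     seed: int = 0) -> LabeledDataset:
    """Render ``n_per_class`` spectra for every recipe, reproducibly.

    Each spectrum uses an rng substream keyed on (seed, class index,
    replicate), so the dataset does not depend on generation order.
    """
    if isinstance(recipes, dict):
        recipes = list(recipes.values())
    names = [r.name for r in recipes]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate recipe names: {sorted(names)}")
    if isinstance(n_per_class, int):
        counts = {name: n_per_class for name in names}
    else:
        counts = dict(n_per_class)
    if any(c < 1 for c in counts.values()):
        raise ValueError("n_per_class must be >= 1")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    spectra, labels = [], []
    for ci, recipe in enumerate(recipes):
        for rep in range(counts[recipe.name]):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), ci, rep]))
            sid = f"{recipe.name}_{rep:04d}"
            spectra.append(render_spectrum(recipe, grid, rng, spectrum_id=sid))
            labels.append(recipe.name)
    return LabeledDataset(spectra, labels)


# Table-style subclass composition of the dentine target domain: four sample
# groups with 370/149/217/86 replicates (822 spectra total).
STANDIN_COUNTS = {
    "Mammoth": 370,
    "Asian Elephant": 149,
    "African Elephant": 217,
    "Unknown Elephant": 86,
}


def make_ivory_standin(seed: int = 0, grid: np.ndarray | None = None) -> LabeledDataset:
    """A synthetic stand-in for the four-subclass dentine target dataset.

    This is generated data, not the real museum-specimen dataset: one
    mammoth-like class and three elephant-like variants (small amplitude
    perturbations of the shared elephant recipe), with the group sizes of the
    real collection. Subclass annotations map the three elephant variants to
    an aggregated class via :func:`protospec.spectra_io.aggregate_classes`.
    """
    base = ivory_recipes()
    mam, ele = base["mammoth_like"], base["elephant_like"]

    def variant(name: str, scale: float) -> ClassRecipe:
        peaks = (PeakSpec(ele.peaks[0].center, ele.peaks[0].amplitude * scale,
                          ele.peaks[0].fwhm), *ele.peaks[1:])
        return ClassRecipe(name, peaks, ele.baseline_coeffs, ele.noise_sd,
                           ele.center_jitter_sd, ele.amplitude_jitter_rel_sd)

    recipes = [
        ClassRecipe("Mammoth", mam.peaks, mam.baseline_coeffs, mam.noise_sd,
                    mam.center_jitter_sd, mam.amplitude_jitter_rel_sd),
        variant("Asian Elephant", 1.00),
        variant("African Elephant", 0.95),
        variant("Unknown Elephant", 1.05),
    ]
    return generate_dataset(recipes, STANDIN_COUNTS, grid=grid, seed=seed)
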